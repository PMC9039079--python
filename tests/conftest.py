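"""Shared fixtures.

The full synthetic benchmark (780 windows, EEMD feature extraction and
network training) is expensive, so its results are computed lazily once
per session and shared between the learning-sanity and ablation tests.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from epncc import pipeline, synthetic
from epncc.network import TrainConfig


@pytest.fixture(scope="session")
def quiet_morph():
    """CHF-like preset with all stochastic components switched off."""
    return replace(synthetic.CHF_PULMONARY_EDEMA, period_jitter_sd=0.0,
                   amp_jitter_sd=0.0, noise_sd=0.0, drift_amp=0.0)


@pytest.fixture(scope="session")
def small_dataset():
    """Twelve-window dataset (4 windows per class) for fast pipeline tests."""
    return synthetic.generate_dataset((1, 1, 1), 4, seed=11)


@pytest.fixture(scope="session")
def seeded_window():
    rng = np.random.default_rng(5)
    return synthetic.generate_window(synthetic.CHF_PULMONARY_EDEMA, rng)


@pytest.fixture(scope="session")
def benchmark_runs():
    """Lazily cached full-benchmark results keyed by (seed, branches)."""
    features_cache: dict[int, pipeline.FeatureSet] = {}
    accuracy_cache: dict[tuple, float] = {}

    def run(seed: int, branches: tuple[str, ...] = ("time", "freq")) -> float:
        key = (seed, branches)
        if key not in accuracy_cache:
            if seed not in features_cache:
                dataset = synthetic.generate_dataset(seed=seed)
                features_cache[seed] = pipeline.extract_features(dataset)
            result = pipeline.run_benchmark(
                features_cache[seed], branches=branches,
                train_config=TrainConfig(seed=seed))
            accuracy_cache[key] = float(result.report.accuracy)
        return accuracy_cache[key]

    return run
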