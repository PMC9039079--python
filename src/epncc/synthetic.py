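"""Seeded synthetic PPG generator.

Produces pulse windows with the geometry and bookkeeping of the ICU pulse
classification experiment this package targets: three clinical classes
(CHF pulmonary edema, respiratory failure, cardiogenic shock) with distinct
per-period morphology, 39 record groups split 16/10/13 across the classes,
20 windows per group (780 windows total), each window being 5 pulse periods
of 90 samples at 125 Hz (450 points).

Each pulse period is a sum of two Gaussian bumps — a systolic peak and a
dicrotic (reflected) wave — which is a standard low-order surrogate for PPG
morphology.  Baseline wander is a low-frequency sinusoid, measurement noise
is additive white Gaussian.  Amplitude jitter acts per window (so the five
periods inside a window stay identical when timing jitter and noise are
off); timing jitter perturbs each period's bump locations independently.

All randomness flows from one integer seed through a per-group
``numpy.random.SeedSequence`` child stream, so datasets are bit-reproducible
and groups are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ParameterError

FS_DEFAULT = 125.0
PERIOD_LEN_DEFAULT = 90
PERIODS_PER_WINDOW_DEFAULT = 5
GROUP_COUNTS_DEFAULT = (16, 10, 13)
WINDOWS_PER_GROUP_DEFAULT = 20

CLASS_NAMES = ("chf_pulmonary_edema", "respiratory_failure", "cardiogenic_shock")


@dataclass(frozen=True)
class ClassMorphology:
    """Per-period pulse shape parameters for one clinical class.

    Locations and widths are fractions of the period; amplitudes are in
    arbitrary units; ``period_jitter_sd`` is in samples.
    """

    class_label: int
    systolic_amp: float
    systolic_loc: float
    systolic_width: float
    dicrotic_amp: float
    dicrotic_loc: float
    dicrotic_width: float
    period_jitter_sd: float = 1.0
    amp_jitter_sd: float = 0.05
    noise_sd: float = 0.02
    drift_amp: float = 0.10
    drift_freq: float = 0.2

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1, 2):
            raise ParameterError("class_label must be 0, 1 or 2")
        if self.systolic_amp < 0:
            raise ParameterError("systolic_amp must be non-negative")
        if self.dicrotic_amp < 0:
            raise ParameterError("dicrotic_amp must be non-negative")
        if not (0 < self.systolic_loc < 1 and 0 < self.dicrotic_loc < 1):
            raise ParameterError("bump locations must lie in (0, 1)")
        if self.systolic_loc >= self.dicrotic_loc:
            raise ParameterError("systolic peak must precede the dicrotic wave")
        if self.systolic_width <= 0 or self.dicrotic_width <= 0:
            raise ParameterError("bump widths must be positive")
        for name in ("period_jitter_sd", "amp_jitter_sd", "noise_sd",
                     "drift_amp", "drift_freq"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


# Built-in presets. The three classes differ in peak timing, peak width and
# the prominence/position of the dicrotic wave (the shapes a clinician would
# read as distinct waveform envelopes); amplitudes are in arbitrary units.
CHF_PULMONARY_EDEMA = ClassMorphology(
    class_label=0,
    systolic_amp=1.0, systolic_loc=0.20, systolic_width=0.060,
    dicrotic_amp=0.35, dicrotic_loc=0.55, dicrotic_width=0.090,
)
RESPIRATORY_FAILURE = ClassMorphology(
    class_label=1,
    systolic_amp=1.0, systolic_loc=0.30, systolic_width=0.110,
    dicrotic_amp=0.15, dicrotic_loc=0.70, dicrotic_width=0.130,
)
CARDIOGENIC_SHOCK = ClassMorphology(
    class_label=2,
    systolic_amp=0.80, systolic_loc=0.20, systolic_width=0.042,
    dicrotic_amp=0.45, dicrotic_loc=0.48, dicrotic_width=0.070,
    noise_sd=0.016,
)
CLASS_PRESETS = (CHF_PULMONARY_EDEMA, RESPIRATORY_FAILURE, CARDIOGENIC_SHOCK)


def one_hot(class_label: int) -> np.ndarray:
    """Map a class index to its one-hot code ([1 0 0] = CHF pulmonary edema,
    [0 1 0] = respiratory failure, [0 0 1] = cardiogenic shock)."""
    code = np.zeros(3)
    code[class_label] = 1.0
    return code


@dataclass
class SyntheticDataset:
    """A generated window collection plus its bookkeeping."""

    signals: np.ndarray          # (n_windows, window_len)
    labels: np.ndarray           # (n_windows, 3) one-hot
    group_ids: np.ndarray        # (n_windows,) global group index
    class_ids: np.ndarray        # (n_windows,) argmax of labels
    fs: float = FS_DEFAULT
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.signals.shape[0]

    @property
    def window_len(self) -> int:
        return self.signals.shape[1]


def generate_period(morph: ClassMorphology, rng: np.random.Generator,
                    period_len: int = PERIOD_LEN_DEFAULT) -> np.ndarray:
    """One pulse period: systolic + dicrotic Gaussian bumps with jitter.

    Amplitude jitter scales both bumps by a common factor 1 + N(0, amp_sd);
    timing jitter shifts both bump centres by N(0, period_sd) samples.
    """
    t = np.arange(period_len) / period_len
    shift = (rng.normal(0.0, morph.period_jitter_sd) / period_len
             if morph.period_jitter_sd > 0 else 0.0)
    scale = (1.0 + rng.normal(0.0, morph.amp_jitter_sd)
             if morph.amp_jitter_sd > 0 else 1.0)
    sys_bump = morph.systolic_amp * np.exp(
        -0.5 * ((t - morph.systolic_loc - shift) / morph.systolic_width) ** 2)
    dic_bump = morph.dicrotic_amp * np.exp(
        -0.5 * ((t - morph.dicrotic_loc - shift) / morph.dicrotic_width) ** 2)
    return scale * (sys_bump + dic_bump)


def generate_window(morph: ClassMorphology, rng: np.random.Generator,
                    periods: int = PERIODS_PER_WINDOW_DEFAULT,
                    period_len: int = PERIOD_LEN_DEFAULT,
                    fs: float = FS_DEFAULT) -> np.ndarray:
    """One sample window: ``periods`` concatenated periods + drift + noise.

    The amplitude jitter is drawn once per window, so with zero timing
    jitter and zero noise the periods inside a window are identical.
    """
    scale = (1.0 + rng.normal(0.0, morph.amp_jitter_sd)
             if morph.amp_jitter_sd > 0 else 1.0)
    per_period = replace(morph, amp_jitter_sd=0.0)
    window = np.concatenate(
        [generate_period(per_period, rng, period_len) for _ in range(periods)])
    window *= scale
    n = window.size
    if morph.drift_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(n) / fs
        window = window + morph.drift_amp * np.sin(
            2 * np.pi * morph.drift_freq * tt + phase)
    if morph.noise_sd > 0:
        window = window + rng.normal(0.0, morph.noise_sd, size=n)
    return window


def generate_record(morph: ClassMorphology, n_periods: int,
                    rng: np.random.Generator | None = None,
                    period_len: int = PERIOD_LEN_DEFAULT,
                    fs: float = FS_DEFAULT) -> np.ndarray:
    """A continuous record of ``n_periods`` concatenated periods.

    With all jitter/noise/drift parameters zero the record is exactly
    periodic with period ``period_len``, which pins peak locations for
    segmentation tests.
    """
    if n_periods < 1:
        raise ParameterError("n_periods must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    record = np.concatenate(
        [generate_period(morph, rng, period_len) for _ in range(n_periods)])
    n = record.size
    if morph.drift_amp > 0:
        tt = np.arange(n) / fs
        record = record + morph.drift_amp * np.sin(
            2 * np.pi * morph.drift_freq * tt)
    if morph.noise_sd > 0:
        record = record + rng.normal(0.0, morph.noise_sd, size=n)
    return record


def generate_dataset(group_counts: tuple[int, int, int] = GROUP_COUNTS_DEFAULT,
                     windows_per_group: int = WINDOWS_PER_GROUP_DEFAULT,
                     seed: int = 0,
                     morphologies: tuple[ClassMorphology, ...] = CLASS_PRESETS,
                     periods_per_window: int = PERIODS_PER_WINDOW_DEFAULT,
                     period_len: int = PERIOD_LEN_DEFAULT,
                     fs: float = FS_DEFAULT) -> SyntheticDataset:
    """Generate the full labelled window collection.

    Total windows = sum(group_counts) * windows_per_group; defaults give
    (16 + 10 + 13) * 20 = 780. Each group gets its own child RNG stream
    derived from ``seed``, so the dataset is reproducible bit-for-bit.
    """
    if len(group_counts) != len(morphologies):
        raise ParameterError("one group count per morphology is required")
    if any(c < 1 for c in group_counts) or windows_per_group < 1:
        raise ParameterError("group counts and windows_per_group must be >= 1")

    signals, labels, group_ids, class_ids = [], [], [], []
    group_id = 0
    for morph, count in zip(morphologies, group_counts):
        for _ in range(count):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(group_id,)))
            for _ in range(windows_per_group):
                signals.append(generate_window(
                    morph, rng, periods_per_window, period_len, fs))
                labels.append(one_hot(morph.class_label))
                group_ids.append(group_id)
                class_ids.append(morph.class_label)
            group_id += 1

    return SyntheticDataset(
        signals=np.asarray(signals),
        labels=np.asarray(labels),
        group_ids=np.asarray(group_ids, dtype=int),
        class_ids=np.asarray(class_ids, dtype=int),
        fs=fs,
        seed=seed,
        meta={"group_counts": tuple(group_counts),
              "windows_per_group": windows_per_group,
              "periods_per_window": periods_per_window,
              "period_len": period_len},
    )
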