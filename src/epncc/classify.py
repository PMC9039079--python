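"""Dataset splitting, feature fusion, and evaluation metrics.

The experiment's bookkeeping: a stratified seeded 70/30 split (780 windows
-> 546 train / 234 test under the default dataset), per-stream
standardization with training-set statistics, and the per-class
recall / precision / F-measure / accuracy report computed from the
argmax confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .exceptions import ParameterError
from .network import ClassifierModel

VARIANCE_FLOOR = 1e-8


def split_dataset(n_samples: int, fraction: float, labels: np.ndarray,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified seeded train/test index split.

    |train| = round(fraction * n); the split is disjoint, exhaustive and
    stratified by class, so 780 samples at fraction 0.7 give 546/234.
    """
    if not (0 < fraction < 1):
        raise ParameterError("fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    y = labels.argmax(axis=1) if labels.ndim == 2 else labels
    if y.shape[0] != n_samples:
        raise ParameterError("labels must have one entry per sample")
    counts = np.bincount(y)
    if np.any(counts[np.unique(y)] < 2):
        raise ParameterError("every class needs at least 2 samples to stratify")
    train_idx, test_idx = train_test_split(
        np.arange(n_samples), train_size=fraction, stratify=y,
        random_state=seed)
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class NormStats:
    """Per-coordinate training-set mean and (floored) standard deviation."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "NormStats":
        std = x.std(axis=0)
        return cls(mean=x.mean(axis=0),
                   std=np.sqrt(np.maximum(std ** 2, VARIANCE_FLOOR)))

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


def fuse_features(time_feats: np.ndarray, freq_feats: np.ndarray,
                  train_stats: tuple[NormStats, NormStats]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Standardize both streams with training statistics; keep them
    separate (one per conv branch).  Zero-variance coordinates are floored
    at sqrt(1e-8), so a constant coordinate maps to 0 rather than erroring.
    """
    ts, fs_ = train_stats
    return ts.apply(np.asarray(time_feats, dtype=float)), \
        fs_.apply(np.asarray(freq_feats, dtype=float))


def f_measure(recall_pct: float, precision_pct: float) -> float:
    """Harmonic mean of recall and precision (both in %), 2 decimals.

    Defined as 0 when both inputs are 0 (reporting convention)."""
    if not (0 <= recall_pct <= 100 and 0 <= precision_pct <= 100):
        raise ParameterError("recall and precision must lie in [0, 100]")
    if recall_pct == 0 and precision_pct == 0:
        return 0.0
    return round(2 * recall_pct * precision_pct / (recall_pct + precision_pct),
                 2)


@dataclass
class EvalReport:
    """Confusion matrix (rows = true class) and derived metrics in %.

    A class absent from the test set gets ``None`` for its metrics rather
    than a NaN."""

    confusion: np.ndarray
    recall: list[float | None]
    precision: list[float | None]
    f_score: list[float | None]
    accuracy: float
    class_names: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "recall_pct": self.recall,
            "precision_pct": self.precision,
            "f_measure_pct": self.f_score,
            "accuracy_pct": self.accuracy,
            "class_names": list(self.class_names),
            **self.extra,
        }


def report_from_confusion(confusion: np.ndarray,
                          class_names: tuple[str, ...] = ()) -> EvalReport:
    """Per-class recall/precision/F and overall accuracy from counts."""
    c = np.asarray(confusion, dtype=int)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ParameterError("confusion matrix must be square")
    total = c.sum()
    if total == 0:
        raise ParameterError("empty confusion matrix")
    recall, precision, f_score = [], [], []
    for k in range(c.shape[0]):
        tp = c[k, k]
        row = c[k].sum()
        col = c[:, k].sum()
        r = 100.0 * tp / row if row > 0 else None
        p = 100.0 * tp / col if col > 0 else None
        recall.append(round(r, 2) if r is not None else None)
        precision.append(round(p, 2) if p is not None else None)
        if r is None or p is None:
            f_score.append(None)
        else:
            f_score.append(f_measure(r, p))
    accuracy = round(100.0 * np.trace(c) / total, 2)
    return EvalReport(confusion=c, recall=recall, precision=precision,
                      f_score=f_score, accuracy=accuracy,
                      class_names=class_names)


def evaluate(model: ClassifierModel, streams: list[np.ndarray],
             labels: np.ndarray,
             class_names: tuple[str, ...] = ()) -> EvalReport:
    """Confusion matrix and metrics of argmax predictions on a test set."""
    y_true = np.asarray(labels)
    if y_true.ndim == 2:
        y_true = y_true.argmax(axis=1)
    y_pred = model.predict(streams)
    k = model.n_classes
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y_true, y_pred), 1)
    return report_from_confusion(confusion, class_names)
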