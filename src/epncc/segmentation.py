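"""Pulse peak detection and multi-period sample assembly.

A sample is a matrix of M consecutive pulse periods, each a fixed-length
slice of L samples starting at a detected systolic peak (defaults M=5,
L=90 at 125 Hz, i.e. a 450-point window).  Periods are fixed-length slices
rather than resampled beats; irregular true periods are truncated or
overrun by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import ParameterError

FS_DEFAULT = 125.0
MIN_PERIOD_S_DEFAULT = 0.4
PROMINENCE_FRAC_DEFAULT = 0.25


@dataclass
class PeriodMatrix:
    """M stacked pulse periods of L samples each (row m = period m)."""

    values: np.ndarray   # (M, L)
    fs: float
    start_index: int     # offset of row 0 in the source record

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ParameterError("PeriodMatrix needs M >= 1 rows, L >= 2 cols")

    @property
    def n_periods(self) -> int:
        return self.values.shape[0]

    @property
    def period_len(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Row-major length-M*L vector (the conv-branch input layout)."""
        return self.values.reshape(-1)


def detect_peaks(signal: np.ndarray, fs: float = FS_DEFAULT,
                 min_period_s: float = MIN_PERIOD_S_DEFAULT,
                 prominence_frac: float = PROMINENCE_FRAC_DEFAULT) -> np.ndarray:
    """Systolic peak indices: local maxima at least ``min_period_s`` apart
    with prominence >= ``prominence_frac`` of the signal range.

    The defaults (0.4 s, 0.25) cover heart rates up to 150 bpm and reject
    dicrotic bumps.  A flat or empty signal yields no peaks.
    """
    signal = np.asarray(signal, dtype=float)
    if fs <= 0 or min_period_s <= 0:
        raise ParameterError("fs and min_period_s must be positive")
    if signal.size < 2:
        return np.array([], dtype=int)
    rng_ = float(np.ptp(signal))
    if rng_ == 0.0:
        return np.array([], dtype=int)
    distance = max(1, int(round(min_period_s * fs)))
    peaks, _ = find_peaks(signal, distance=distance,
                          prominence=prominence_frac * rng_)
    return peaks.astype(int)


def build_windows(signal: np.ndarray, peaks: np.ndarray, M: int = 5,
                  L: int = 90, fs: float = FS_DEFAULT) -> list[PeriodMatrix]:
    """Assemble non-overlapping M-period samples from detected peaks.

    Each sample consumes M consecutive peaks; row m is the L samples
    starting at peak m.  The next sample starts at the peak following the
    last consumed period, so windows never share beats (no leakage between
    later train/test splits).  Runs where any period would extend past the
    record end are discarded, as is an incomplete tail.
    """
    signal = np.asarray(signal, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    if M < 1 or L < 1:
        raise ParameterError("M and L must be >= 1")
    if np.any(np.diff(peaks) <= 0):
        raise ParameterError("peaks must be strictly increasing")

    windows: list[PeriodMatrix] = []
    i = 0
    while i + M <= peaks.size:
        run = peaks[i:i + M]
        if run[-1] + L > signal.size:
            break
        rows = np.stack([signal[p:p + L] for p in run])
        windows.append(PeriodMatrix(rows, fs=fs, start_index=int(run[0])))
        i += M
    return windows


def segment(signal: np.ndarray, fs: float = FS_DEFAULT, M: int = 5,
            L: int = 90, min_period_s: float = MIN_PERIOD_S_DEFAULT,
            prominence_frac: float = PROMINENCE_FRAC_DEFAULT
            ) -> list[PeriodMatrix]:
    """Peak detection followed by window assembly (the one-call form)."""
    peaks = detect_peaks(signal, fs, min_period_s, prominence_frac)
    return build_windows(signal, peaks, M=M, L=L, fs=fs)
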