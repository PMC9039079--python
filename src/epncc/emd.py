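"""Empirical mode decomposition, its noise-assisted ensemble variant, and
coherence-based IMF screening.

EMD sifts a signal into intrinsic mode functions (IMFs) ordered fastest to
slowest, using cubic-spline envelopes through the local extrema with mirror
boundary extension.  EEMD averages the IMFs of many white-noise-perturbed
copies of the signal, which suppresses mode mixing at the cost of a small
residual noise floor of order noise_sd / sqrt(ensemble_size).

Screening keeps the IMFs that actually represent the signal, ranked by the
coherence coefficient

    mu = sum f_k s_k / sqrt(sum f_k^2 * sum s_k^2),

where f_k is the IMF and s_k is, by default, the difference between the
original signal and the IMF.  A ``mode="signal"`` option correlates the IMF
against the signal itself for users expecting conventional correlation
screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import DegenerateInputError, ParameterError

SIFT_SD_THRESHOLD = 0.2
MAX_SIFTS = 10
MAX_IMFS_DEFAULT = 10
ENSEMBLE_SIZE_DEFAULT = 100
NOISE_SD_FRAC_DEFAULT = 0.2
COHERENCE_THRESHOLD_DEFAULT = 0.1


@dataclass
class IMFSet:
    """Ordered IMFs plus residual; optionally per-IMF coherence scores."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    coherence: np.ndarray | None = None
    noise_sd: float = 0.0
    ensemble_size: int = 1
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (interior samples)."""
    core = x[1:-1]
    maxima = np.flatnonzero((core > x[:-2]) & (core > x[2:])) + 1
    minima = np.flatnonzero((core < x[:-2]) & (core < x[2:])) + 1
    return maxima, minima


def _envelope(t_ext: np.ndarray, v_ext: np.ndarray, n: int,
              grid: np.ndarray) -> np.ndarray:
    """Spline through extrema, mirror-extended past both record ends."""
    if t_ext.size >= 2:
        # reflect up to two extrema about each endpoint
        k = min(2, t_ext.size)
        left_t = -t_ext[:k][::-1]
        left_v = v_ext[:k][::-1]
        right_t = 2 * (n - 1) - t_ext[-k:][::-1]
        right_v = v_ext[-k:][::-1]
        t_full = np.concatenate([left_t, t_ext, right_t])
        v_full = np.concatenate([left_v, v_ext, right_v])
        # mirroring can duplicate an endpoint-located extremum
        t_full, idx = np.unique(t_full, return_index=True)
        v_full = v_full[idx]
    else:
        t_full, v_full = t_ext, v_ext
    if t_full.size >= 4:
        return CubicSpline(t_full, v_full)(grid)
    if t_full.size >= 2:
        return np.interp(grid, t_full, v_full)
    return np.full(n, v_full[0] if v_full.size else 0.0)


def _sift_imf(x: np.ndarray, grid: np.ndarray,
              sd_threshold: float = SIFT_SD_THRESHOLD) -> np.ndarray | None:
    """Extract one IMF from ``x``, or None when ``x`` has too few extrema.

    Sifting stops when the standard SD criterion drops below
    ``sd_threshold`` or after ``MAX_SIFTS`` passes.
    """
    n = x.size
    h = x
    for _ in range(MAX_SIFTS):
        maxima, minima = _local_extrema(h)
        if maxima.size < 1 or minima.size < 1 or maxima.size + minima.size < 3:
            return None if h is x else h
        upper = _envelope(maxima, h[maxima], n, grid)
        lower = _envelope(minima, h[minima], n, grid)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = float(np.sum(h * h))
        if denom > 0:
            sd = float(np.sum((h - h_new) ** 2)) / denom
        else:
            sd = 0.0
        h = h_new
        if sd < sd_threshold:
            break
    return h


def emd_decompose(signal: np.ndarray,
                  max_imfs: int = MAX_IMFS_DEFAULT,
                  sift_sd_threshold: float = SIFT_SD_THRESHOLD) -> IMFSet:
    """Plain EMD. Returns IMFs (fastest first) and the residual trend.

    The decomposition is exactly additive: sum(imfs) + residual == signal
    to rounding error.  A constant signal yields no IMFs and is returned
    whole as the residual.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ParameterError("signal must be 1-D with at least 8 samples")
    grid = np.arange(x.size, dtype=float)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residual)
        if maxima.size + minima.size < 3:
            break
        imf = _sift_imf(residual, grid, sift_sd_threshold)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return IMFSet(imfs=imfs, residual=residual)


def eemd_decompose(signal: np.ndarray,
                   ensemble_size: int = ENSEMBLE_SIZE_DEFAULT,
                   noise_sd_frac: float = NOISE_SD_FRAC_DEFAULT,
                   seed: int = 0,
                   max_imfs: int = MAX_IMFS_DEFAULT) -> IMFSet:
    """Ensemble EMD: average the k-th IMFs of noise-perturbed copies.

    Noise is white Gaussian with sd ``noise_sd_frac * std(signal)``; a
    member that produced fewer IMFs than another contributes zeros for the
    missing ones.  Deterministic under a fixed seed.
    """
    x = np.asarray(signal, dtype=float)
    if ensemble_size < 1:
        raise ParameterError("ensemble_size must be >= 1")
    if noise_sd_frac < 0:
        raise ParameterError("noise_sd_frac must be non-negative")
    sigma = noise_sd_frac * float(np.std(x))
    if ensemble_size == 1 and sigma == 0.0:
        out = emd_decompose(x, max_imfs=max_imfs)
        out.ensemble_size = 1
        out.seed = seed
        return out

    rng = np.random.default_rng(seed)
    member_imfs: list[list[np.ndarray]] = []
    member_residuals: list[np.ndarray] = []
    for _ in range(ensemble_size):
        noisy = x + rng.normal(0.0, sigma, size=x.size) if sigma > 0 else x
        dec = emd_decompose(noisy, max_imfs=max_imfs)
        member_imfs.append(dec.imfs)
        member_residuals.append(dec.residual)

    n_modes = max((len(m) for m in member_imfs), default=0)
    imfs = []
    for k in range(n_modes):
        acc = np.zeros(x.size)
        for m in member_imfs:
            if k < len(m):
                acc += m[k]
        imfs.append(acc / ensemble_size)
    residual = np.mean(member_residuals, axis=0)
    return IMFSet(imfs=imfs, residual=residual, noise_sd=sigma,
                  ensemble_size=ensemble_size, seed=seed)


def coherence(imf: np.ndarray, signal: np.ndarray,
              mode: str = "difference") -> float:
    """Coherence mu between an IMF f_k and the source signal x.

    mode="difference" (default): s_k = x - f_k, the complement of the IMF;
    mode="signal": s_k = x, plain normalized correlation.
    """
    f = np.asarray(imf, dtype=float)
    x = np.asarray(signal, dtype=float)
    if f.shape != x.shape:
        raise ParameterError("imf and signal must have equal length")
    if mode == "difference":
        s = x - f
    elif mode == "signal":
        s = x
    else:
        raise ParameterError(f"unknown coherence mode {mode!r}")
    f_norm2 = float(np.dot(f, f))
    s_norm2 = float(np.dot(s, s))
    if f_norm2 == 0.0 or s_norm2 == 0.0:
        raise DegenerateInputError("coherence undefined for zero-norm operand")
    return float(np.dot(f, s) / np.sqrt(f_norm2 * s_norm2))


def score_coherence(imfset: IMFSet, signal: np.ndarray,
                    mode: str = "difference") -> IMFSet:
    """Attach a coherence score to every IMF (in place; returns the set).

    An IMF that is identically zero (possible for averaged ensemble modes)
    gets score -inf so screening can never select it."""
    scores = []
    for f in imfset.imfs:
        try:
            scores.append(coherence(f, signal, mode=mode))
        except DegenerateInputError:
            scores.append(-np.inf)
    imfset.coherence = np.asarray(scores)
    return imfset


def screen_imfs(imfset: IMFSet,
                threshold: float = COHERENCE_THRESHOLD_DEFAULT) -> IMFSet:
    """Keep IMFs with coherence >= threshold, preserving order.

    If every IMF falls below the threshold the single best one (argmax of
    mu) is kept, so downstream feature extraction always has input.
    """
    if imfset.n_imfs == 0:
        raise DegenerateInputError("cannot screen an empty IMF set")
    if imfset.coherence is None or len(imfset.coherence) != imfset.n_imfs:
        raise ParameterError("coherence must be scored before screening")
    keep = np.flatnonzero(imfset.coherence >= threshold)
    if keep.size == 0:
        keep = np.array([int(np.argmax(imfset.coherence))])
    return IMFSet(
        imfs=[imfset.imfs[i] for i in keep],
        residual=imfset.residual,
        coherence=imfset.coherence[keep],
        noise_sd=imfset.noise_sd,
        ensemble_size=imfset.ensemble_size,
        seed=imfset.seed,
        meta={**imfset.meta, "kept_indices": keep.tolist(),
              "threshold": threshold},
    )


def zero_crossings(v: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros."""
    s = np.sign(v[v != 0])
    return int(np.sum(s[1:] != s[:-1]))
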