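"""Power-normalized cepstral coefficients over EEMD-screened IMFs.

The frequency-domain feature of the pipeline.  For each screened IMF:

  1. one-sided periodogram power spectrum P(w) (Parseval-normalized);
  2. Gammatone filterbank band powers P(w_g), the filterbank acting as
     spectral weights on the power estimate (not a waveform convolution);
  3. power normalization U_n = P(w_g) / mean-band-power, so mean(U) = 1
     and the features are invariant to the window's overall amplitude;
  4. power-law compression Pow_n = U_n ** theta with 0 < theta < 1
     (default 1/15, the conventional PNCC exponent);
  5. orthonormal DCT-II, keeping the first ``n_ceps`` coefficients.

The Gammatone impulse response is g(t) = a t^(n-1) exp(-2 pi b t)
cos(2 pi f0 t + phi); centre frequencies are spaced on an ERB-rate scale
over the pulse band (default 0.5-40 Hz).  The audio ERB constants put
bandwidths of tens of Hz on sub-Hz centres, which is meaningless below
40 Hz, so the ERB law keeps its form f0/Q + B_min with the audio Q = 9.26
but a band-appropriate minimum bandwidth B_min = 0.3 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct
from scipy.signal import welch as _welch

from .emd import (COHERENCE_THRESHOLD_DEFAULT, eemd_decompose,
                  score_coherence, screen_imfs)
from .exceptions import DegenerateInputError, ParameterError
from .segmentation import PeriodMatrix

THETA_DEFAULT = 1.0 / 15.0
N_CEPS_DEFAULT = 13
N_FILTERS_DEFAULT = 20
GAMMATONE_ORDER_DEFAULT = 4
FMIN_DEFAULT = 0.5
FMAX_DEFAULT = 40.0
ERB_Q = 9.26449
ERB_BMIN = 0.3          # Hz; pulse-band minimum bandwidth (audio uses 24.7)
ERB_BROADENING = 1.019  # classic Gammatone b = 1.019 * ERB(f0)


def power_spectrum(x: np.ndarray, mode: str = "periodogram",
                   fs: float = 125.0) -> np.ndarray:
    """One-sided power spectrum on bins 0..N/2.

    ``periodogram`` mode returns |DFT|^2 / N with interior bins doubled, so
    the one-sided sum equals the signal energy sum(x^2) (Parseval).
    ``welch`` mode returns scipy's Welch estimate on the same bin count
    (a smoother estimate; its normalization is a density, not an energy).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ParameterError("input must be 1-D with at least 8 samples")
    n = x.size
    if mode == "periodogram":
        spec = np.abs(np.fft.rfft(x)) ** 2 / n
        spec[1:(n + 1) // 2] *= 2.0
        return spec
    if mode == "welch":
        _, spec = _welch(x, fs=fs, nperseg=min(n, 256), nfft=n)
        return spec
    raise ParameterError(f"unknown power spectrum mode {mode!r}")


def erb_bandwidth(f0: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth law scaled to the pulse band."""
    return np.asarray(f0) / ERB_Q + ERB_BMIN


def erb_space(fmin: float, fmax: float, n: int) -> np.ndarray:
    """``n`` centre frequencies uniformly spaced on the ERB-rate scale.

    The ERB-rate of f under ERB(f) = f/Q + Bmin is Q*log(1 + f/(Q*Bmin));
    inverting a uniform grid on that scale gives the centres.
    """
    def rate(f):
        return ERB_Q * np.log1p(f / (ERB_Q * ERB_BMIN))

    def inv(r):
        return ERB_Q * ERB_BMIN * np.expm1(r / ERB_Q)

    return inv(np.linspace(rate(fmin), rate(fmax), n))


@dataclass
class GammatoneBank:
    """Gammatone filterbank realized as spectral magnitude-squared weights."""

    n_filters: int
    order: int
    center_freqs: np.ndarray   # Hz, strictly increasing
    bandwidths: np.ndarray     # Hz
    amplitude: float
    phase: float
    fs: float
    freq_responses: np.ndarray  # (n_filters, n_bins) non-negative weights
    meta: dict = field(default_factory=dict)


def gammatone_ir(f0: float, b: float, order: int = GAMMATONE_ORDER_DEFAULT,
                 fs: float = 125.0, amplitude: float = 1.0,
                 phase: float = 0.0) -> np.ndarray:
    """Sampled impulse response a t^(n-1) e^(-2 pi b t) cos(2 pi f0 t + phi).

    Truncated where the envelope has decayed to ~1e-6 of its peak, then
    peak-normalized (max |g| = 1).
    """
    if b <= 0 or f0 <= 0:
        raise ParameterError("centre frequency and bandwidth must be positive")
    # envelope peak at t* = (n-1)/(2 pi b); ~14/(2 pi b) past it the
    # exponential alone is < 1e-6
    t_end = (order - 1 + 14.0) / (2 * np.pi * b)
    t = np.arange(0.0, t_end, 1.0 / fs)
    g = amplitude * t ** (order - 1) * np.exp(-2 * np.pi * b * t) \
        * np.cos(2 * np.pi * f0 * t + phase)
    peak = np.max(np.abs(g))
    if peak > 0:
        g = g / peak
    return g


def build_gammatone_bank(n_filters: int = N_FILTERS_DEFAULT,
                         fmin: float = FMIN_DEFAULT,
                         fmax: float = FMAX_DEFAULT,
                         order: int = GAMMATONE_ORDER_DEFAULT,
                         fs: float = 125.0,
                         n_bins: int = 226,
                         amplitude: float = 1.0,
                         phase: float = 0.0) -> GammatoneBank:
    """ERB-spaced Gammatone bank sampled at the spectrum's bin frequencies.

    ``n_bins`` must equal the length of the one-sided power spectra the
    bank will weight (N/2 + 1 for N-sample windows; 226 for N = 450).
    """
    if not (0 < fmin < fmax < fs / 2):
        raise ParameterError("need 0 < fmin < fmax < fs/2")
    if n_filters < 1 or order < 1 or n_bins < 2:
        raise ParameterError("n_filters, order and n_bins must be >= 1")
    f0s = erb_space(fmin, fmax, n_filters)
    bws = ERB_BROADENING * erb_bandwidth(f0s)
    n_sig = 2 * (n_bins - 1)
    bin_freqs = np.arange(n_bins) * fs / n_sig
    responses = np.empty((n_filters, n_bins))
    for i, (f0, b) in enumerate(zip(f0s, bws)):
        g = gammatone_ir(f0, b, order, fs, amplitude, phase)
        # DFT evaluated at the spectrum's exact bin frequencies
        t = np.arange(g.size) / fs
        spectrum = np.exp(-2j * np.pi * np.outer(bin_freqs, t)) @ g
        responses[i] = np.abs(spectrum) ** 2
    return GammatoneBank(n_filters=n_filters, order=order, center_freqs=f0s,
                         bandwidths=bws, amplitude=amplitude, phase=phase,
                         fs=fs, freq_responses=responses,
                         meta={"fmin": fmin, "fmax": fmax, "n_bins": n_bins})


def band_powers(spectrum: np.ndarray, bank: GammatoneBank) -> np.ndarray:
    """Per-filter weighted sum of the power spectrum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[0] != bank.freq_responses.shape[1]:
        raise ParameterError("spectrum bin count does not match the bank")
    return bank.freq_responses @ spectrum


def power_normalize(powers: np.ndarray) -> np.ndarray:
    """U_n = P_n / mean(P): unit-mean band powers (amplitude-invariant)."""
    powers = np.asarray(powers, dtype=float)
    mean = powers.mean()
    if mean <= 0:
        raise DegenerateInputError("all band powers are zero; cannot normalize")
    return powers / mean


def power_law(u: np.ndarray, theta: float = THETA_DEFAULT) -> np.ndarray:
    """Elementwise compression U ** theta, 0 < theta < 1."""
    u = np.asarray(u, dtype=float)
    if not (0 < theta < 1):
        raise ParameterError("theta must lie strictly in (0, 1)")
    if np.any(u < 0):
        raise ParameterError("band powers must be non-negative")
    return u ** theta


def cepstral_dct(pow_n: np.ndarray, n_ceps: int = N_CEPS_DEFAULT) -> np.ndarray:
    """First ``n_ceps`` coefficients of the orthonormal DCT-II."""
    pow_n = np.asarray(pow_n, dtype=float)
    if n_ceps < 1 or n_ceps > pow_n.size:
        raise ParameterError("n_ceps must lie in 1..len(input)")
    return dct(pow_n, type=2, norm="ortho")[:n_ceps]


def inverse_cepstral_dct(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cepstral_dct` at full length (round-trip check)."""
    return idct(np.asarray(coeffs, dtype=float), type=2, norm="ortho")


@dataclass
class EPNCCFeatures:
    """Cepstral coefficient matrix, one row per screened IMF."""

    coeffs: np.ndarray   # (n_kept_imfs, n_ceps)
    theta: float
    n_ceps: int
    kept_indices: list[int]
    provenance: dict = field(default_factory=dict)


def epncc_features(window: PeriodMatrix | np.ndarray,
                   ensemble_size: int = 100,
                   noise_sd_frac: float = 0.2,
                   seed: int = 0,
                   coherence_threshold: float = COHERENCE_THRESHOLD_DEFAULT,
                   coherence_mode: str = "difference",
                   bank: GammatoneBank | None = None,
                   theta: float = THETA_DEFAULT,
                   n_ceps: int = N_CEPS_DEFAULT,
                   fs: float = 125.0,
                   max_imfs: int = 10) -> EPNCCFeatures:
    """Full EPNCC front-end for one pulse window.

    EEMD -> coherence screening -> per-IMF periodogram -> Gammatone band
    powers -> power normalization -> power law -> DCT.  Deterministic under
    a fixed seed.  Raises on degenerate (e.g. all-zero) windows rather than
    emitting NaNs.
    """
    x = window.flatten() if isinstance(window, PeriodMatrix) else \
        np.asarray(window, dtype=float).reshape(-1)
    if x.size == 0 or np.all(x == x[0]):
        raise DegenerateInputError("constant or empty window has no EPNCC")
    imfset = eemd_decompose(x, ensemble_size=ensemble_size,
                            noise_sd_frac=noise_sd_frac, seed=seed,
                            max_imfs=max_imfs)
    score_coherence(imfset, x, mode=coherence_mode)
    kept = screen_imfs(imfset, coherence_threshold)
    if bank is None:
        bank = build_gammatone_bank(fs=fs, n_bins=x.size // 2 + 1)
    rows = []
    for f in kept.imfs:
        p = power_spectrum(f, fs=fs)
        u = power_normalize(band_powers(p, bank))
        rows.append(cepstral_dct(power_law(u, theta), n_ceps))
    return EPNCCFeatures(coeffs=np.vstack(rows), theta=theta, n_ceps=n_ceps,
                         kept_indices=kept.meta.get("kept_indices", []),
                         provenance={"ensemble_size": ensemble_size,
                                     "noise_sd_frac": noise_sd_frac,
                                     "seed": seed,
                                     "coherence_threshold": coherence_threshold,
                                     "coherence_mode": coherence_mode})
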