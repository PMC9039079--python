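"""1-D wavelet scattering transform (time-domain feature branch).

A two-order scattering network over a periodic length-N grid: Morlet
band-pass filters at Q1 wavelets per octave (first order) and Q2 (second
order), a Gaussian low-pass phi whose width is set by the invariance scale
T (in seconds at the record's sampling rate), modulus nonlinearities
between layers, and low-pass averaging with subsampling by 2**j (where
2**j <= T in samples) at oversampling factor 0:

    order 0:  x * phi
    order 1:  |x * psi_a1| * phi
    order 2:  ||x * psi_a1| * psi_a2| * phi   with  freq(a2) < freq(a1)

All convolutions are circular (periodic boundary), computed in the
frequency domain.  Each filterbank layer is Littlewood-Paley normalized so
that |phi|^2 + sum |psi|^2 <= 1 on every bin, which makes the whole
transform non-expansive (||Sx|| <= ||x||).  The low-pass has unit DC gain,
so a constant window passes through order 0 unchanged and is annihilated
by every band-pass path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

XI_MAX = 0.40  # highest wavelet centre frequency, cycles/sample


@dataclass(frozen=True)
class ScatteringConfig:
    signal_length: int = 450
    invariance_scale: float = 1.8       # seconds
    quality_factors: tuple[int, int] = (8, 1)
    boundary: str = "periodic"
    fs: float = 125.0
    oversampling_factor: int = 0
    precision: str = "double"

    def __post_init__(self) -> None:
        if self.invariance_scale * self.fs > self.signal_length:
            raise ParameterError(
                "invariance scale exceeds the signal duration")
        if any(q < 1 for q in self.quality_factors):
            raise ParameterError("quality factors must be positive integers")
        if self.boundary != "periodic":
            raise ParameterError("only the periodic boundary is supported")

    @property
    def t_samples(self) -> int:
        """Invariance scale in samples."""
        return int(round(self.invariance_scale * self.fs))

    @property
    def max_scale_j(self) -> int:
        """Largest dyadic scale with 2**j <= T."""
        return int(np.floor(np.log2(self.t_samples)))


@dataclass
class ScatteringBank:
    """Frequency-domain filters for one scattering layer cascade."""

    config: ScatteringConfig
    lowpass: np.ndarray                 # (N,) real, DC gain 1
    psi_by_order: list[np.ndarray]      # per order: (n_filters, N)
    xi_by_order: list[np.ndarray]       # centre freqs (cycles/sample), desc
    stride: int


@dataclass
class ScatteringFeatures:
    """Scattering paths and their averaged coefficients."""

    paths: list[tuple]                  # (order, (k1, ...)) scale indices
    coeffs: np.ndarray                  # (n_paths, n_frames)
    config: ScatteringConfig

    def flatten(self) -> np.ndarray:
        return self.coeffs.reshape(-1)


def _morlet_hat(n: int, xi: float, sigma: float) -> np.ndarray:
    """Frequency response of an analytic Morlet on the length-n grid.

    Gaussian at +xi with the standard corrective term that forces an
    exactly zero mean (response 0 at the DC bin).
    """
    nu = np.arange(n) / n
    nu = np.where(nu > 0.5, nu - 1.0, nu)  # wrapped grid in (-0.5, 0.5]
    main = np.exp(-((nu - xi) ** 2) / (2 * sigma ** 2))
    beta = np.exp(-(xi ** 2) / (2 * sigma ** 2))
    return main - beta * np.exp(-(nu ** 2) / (2 * sigma ** 2))


def build_scattering_bank(config: ScatteringConfig) -> ScatteringBank:
    """Construct the Morlet banks and the Gaussian low-pass.

    Centre frequencies run geometrically from XI_MAX down to 1/2**j at
    2**(1/Q) spacing for each order's quality factor Q.  The scale index k
    of a filter increases as its centre frequency decreases, matching the
    convention that alpha_1 < alpha_2 means "finer scale before coarser".
    """
    n = config.signal_length
    j = config.max_scale_j
    t = config.t_samples
    nu = np.arange(n) / n
    nu_wrapped = np.where(nu > 0.5, nu - 1.0, nu)

    # Gaussian low-pass, unit DC gain, time width ~ T
    sigma_phi = 0.4 / t
    lowpass = np.exp(-(nu_wrapped ** 2) / (2 * sigma_phi ** 2))

    xi_min = 1.0 / 2 ** j
    psi_by_order, xi_by_order = [], []
    for q in config.quality_factors:
        ratio = 2.0 ** (1.0 / q)
        xis = []
        xi = XI_MAX
        while xi >= xi_min:
            xis.append(xi)
            xi /= ratio
        xis = np.asarray(xis)
        sigmas = xis * (ratio - 1.0) / 1.177
        psis = np.stack([_morlet_hat(n, x, s) for x, s in zip(xis, sigmas)])
        # Littlewood-Paley normalization: |phi|^2 + c^2 sum|psi|^2 <= 1
        lp = np.sum(psis ** 2, axis=0)
        mask = lp > 1e-12
        c2 = np.min((1.0 - lowpass[mask] ** 2) / lp[mask])
        psis *= np.sqrt(max(c2, 0.0))
        psi_by_order.append(psis)
        xi_by_order.append(xis)

    stride = max(1, 2 ** (j - config.oversampling_factor))
    return ScatteringBank(config=config, lowpass=lowpass,
                          psi_by_order=psi_by_order, xi_by_order=xi_by_order,
                          stride=stride)


def scattering_transform(window: np.ndarray,
                         config: ScatteringConfig | None = None,
                         bank: ScatteringBank | None = None
                         ) -> ScatteringFeatures:
    """Two-order scattering coefficients of one pulse window.

    Order-2 paths pair a first-order filter with every second-order filter
    of strictly lower centre frequency (the alpha_1 < alpha_2 scale
    ordering).  Outputs are averaged by the low-pass and subsampled by the
    bank stride.
    """
    if bank is None:
        bank = build_scattering_bank(config or ScatteringConfig())
    config = bank.config
    x = np.asarray(window, dtype=float).reshape(-1)
    if x.size != config.signal_length:
        raise ParameterError(
            f"window length {x.size} != configured {config.signal_length}")

    stride = bank.stride
    phi = bank.lowpass
    psi1, psi2 = bank.psi_by_order
    xi1, xi2 = bank.xi_by_order

    def smooth(u_hat):
        return np.real(np.fft.ifft(u_hat * phi))[::stride]

    x_hat = np.fft.fft(x)
    paths: list[tuple] = [(0, ())]
    rows: list[np.ndarray] = [smooth(x_hat)]

    # first order
    u1_hats = []
    for k1 in range(psi1.shape[0]):
        u1 = np.abs(np.fft.ifft(x_hat * psi1[k1]))
        u1_hat = np.fft.fft(u1)
        u1_hats.append(u1_hat)
        paths.append((1, (k1,)))
        rows.append(smooth(u1_hat))

    # second order: centre frequency must strictly decrease along the path
    for k1, u1_hat in enumerate(u1_hats):
        for k2 in range(psi2.shape[0]):
            if xi2[k2] >= xi1[k1]:
                continue
            u2 = np.abs(np.fft.ifft(u1_hat * psi2[k2]))
            paths.append((2, (k1, k2)))
            rows.append(smooth(np.fft.fft(u2)))

    return ScatteringFeatures(paths=paths, coeffs=np.stack(rows),
                              config=config)
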