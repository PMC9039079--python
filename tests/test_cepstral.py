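"""EPNCC front-end stages, each against a direct-formula oracle."""

import numpy as np
import pytest

from epncc import cepstral, emd
from epncc.exceptions import DegenerateInputError, ParameterError


# ---- power spectrum ----------------------------------------------------

def test_parseval_identity():
    rng = np.random.default_rng(0)
    for n in (64, 450):
        x = rng.normal(size=n)
        spec = cepstral.power_spectrum(x)
        assert spec.sum() == pytest.approx(np.sum(x ** 2), rel=1e-9)


def test_zero_vector_has_zero_spectrum():
    assert np.all(cepstral.power_spectrum(np.zeros(450)) == 0.0)


def test_exact_bin_sinusoid_concentrates_in_one_bin():
    n = 450
    k = 30
    x = np.sin(2 * np.pi * k * np.arange(n) / n)
    spec = cepstral.power_spectrum(x)
    others = np.delete(spec, k)
    assert spec[k] == pytest.approx(np.sum(x ** 2), rel=1e-9)
    assert np.max(others) < 1e-12 * spec[k]


# ---- Gammatone bank ----------------------------------------------------

def test_gammatone_impulse_response_starts_at_zero():
    g = cepstral.gammatone_ir(f0=5.0, b=1.0, order=4)
    assert g[0] == 0.0  # t^(n-1) factor with n=4


def test_gammatone_envelope_peak_location():
    """Envelope a t^(n-1) e^(-2 pi b t) peaks at t* = (n-1)/(2 pi b)."""
    order, b, fs = 4, 1.0, 1000.0
    t = np.arange(0, 5, 1 / fs)
    env = t ** (order - 1) * np.exp(-2 * np.pi * b * t)
    t_star = (order - 1) / (2 * np.pi * b)
    assert abs(t[np.argmax(env)] - t_star) <= 1 / fs


@pytest.fixture(scope="module")
def bank():
    return cepstral.build_gammatone_bank(n_bins=226)


def test_bank_centres_increasing_below_nyquist(bank):
    assert np.all(np.diff(bank.center_freqs) > 0)
    assert bank.center_freqs[-1] < bank.fs / 2
    assert bank.freq_responses.shape == (20, 226)
    assert np.all(bank.freq_responses >= 0)


def test_bank_response_peaks_at_centre_frequency(bank):
    bin_width = bank.fs / (2 * (226 - 1))
    argmax_freqs = np.argmax(bank.freq_responses, axis=1) * bin_width
    assert np.all(np.abs(argmax_freqs - bank.center_freqs) <= bin_width)


def test_bad_band_edges_rejected():
    with pytest.raises(ParameterError):
        cepstral.build_gammatone_bank(fmin=0.5, fmax=80.0, fs=125.0)
    with pytest.raises(ParameterError):
        cepstral.build_gammatone_bank(fmin=0.0, fmax=40.0)


# ---- band powers -------------------------------------------------------

def test_band_powers_linearity_and_oracle(bank):
    zero = cepstral.band_powers(np.zeros(226), bank)
    assert np.all(zero == 0.0)

    one_bin = np.zeros(226)
    one_bin[40] = 1.0
    np.testing.assert_allclose(cepstral.band_powers(one_bin, bank),
                               bank.freq_responses[:, 40])

    rng = np.random.default_rng(1)
    spec = rng.uniform(size=226)
    expected = np.array([sum(bank.freq_responses[g, k] * spec[k]
                             for k in range(226))
                         for g in range(bank.n_filters)])
    np.testing.assert_allclose(cepstral.band_powers(spec, bank), expected,
                               rtol=1e-12)

    with pytest.raises(ParameterError):
        cepstral.band_powers(np.ones(100), bank)


# ---- power normalization / power law ----------------------------------

def test_power_normalize_examples():
    np.testing.assert_allclose(cepstral.power_normalize([2.0, 4.0, 6.0]),
                               [0.5, 1.0, 1.5])
    np.testing.assert_allclose(cepstral.power_normalize(np.full(7, 3.3)),
                               np.ones(7))
    rng = np.random.default_rng(2)
    u = cepstral.power_normalize(rng.uniform(0.1, 5.0, size=20))
    assert u.mean() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(DegenerateInputError):
        cepstral.power_normalize(np.zeros(5))


def test_power_law_examples():
    assert cepstral.power_law(np.array([1.0]), 0.3)[0] == 1.0
    assert cepstral.power_law(np.array([0.0]), 0.3)[0] == 0.0
    assert cepstral.power_law(np.array([2.0 ** 15]), 1 / 15)[0] == \
        pytest.approx(2.0, rel=1e-12)
    for bad in (0.0, 1.0, -0.5, 2.0):
        with pytest.raises(ParameterError):
            cepstral.power_law(np.ones(3), bad)


# ---- DCT ---------------------------------------------------------------

def test_dct_of_constant():
    n = 16
    c = 2.5
    coeffs = cepstral.cepstral_dct(np.full(n, c), n_ceps=n)
    assert coeffs[0] == pytest.approx(c * np.sqrt(n), rel=1e-12)
    assert np.max(np.abs(coeffs[1:])) < 1e-12


def test_dct_impulse_matches_cosine_sum():
    x = np.array([1.0, 0.0, 0.0, 0.0])
    n = 4
    # orthonormal DCT-II: y_k = s_k * sum_i x_i cos(pi k (2i+1) / (2n))
    expected = []
    for k in range(n):
        s = np.sqrt(1 / n) if k == 0 else np.sqrt(2 / n)
        expected.append(s * sum(x[i] * np.cos(np.pi * k * (2 * i + 1) / (2 * n))
                                for i in range(n)))
    np.testing.assert_allclose(cepstral.cepstral_dct(x, n_ceps=n), expected,
                               rtol=1e-12)


def test_dct_orthonormal_round_trip():
    rng = np.random.default_rng(3)
    x = rng.normal(size=20)
    coeffs = cepstral.cepstral_dct(x, n_ceps=20)
    np.testing.assert_allclose(cepstral.inverse_cepstral_dct(coeffs), x,
                               atol=1e-10)
    with pytest.raises(ParameterError):
        cepstral.cepstral_dct(x, n_ceps=21)


# ---- composed EPNCC ----------------------------------------------------

def test_epncc_matches_stagewise_oracle_composition():
    """Chain the independent stage formulas on a toy two-tone window and
    compare with the composed feature extractor."""
    n = 64
    t = np.arange(n)
    x = np.sin(2 * np.pi * 12 * t / n) + 0.8 * np.sin(2 * np.pi * 3 * t / n)
    bank = cepstral.build_gammatone_bank(n_filters=8, fmin=1.0, fmax=30.0,
                                         fs=125.0, n_bins=n // 2 + 1)
    feats = cepstral.epncc_features(x, ensemble_size=6, seed=9, bank=bank,
                                    n_ceps=8)

    imfset = emd.eemd_decompose(x, ensemble_size=6, noise_sd_frac=0.2, seed=9)
    emd.score_coherence(imfset, x)
    kept = emd.screen_imfs(imfset, 0.1)
    assert feats.kept_indices == kept.meta["kept_indices"]
    for row, f in zip(feats.coeffs, kept.imfs):
        spec = np.abs(np.fft.rfft(f)) ** 2 / n
        spec[1:n // 2] *= 2
        p = np.array([np.dot(bank.freq_responses[g], spec)
                      for g in range(8)])
        u = p / p.mean()
        pw = u ** (1 / 15)
        expected = [
            (np.sqrt(1 / 8) if k == 0 else np.sqrt(2 / 8))
            * sum(pw[i] * np.cos(np.pi * k * (2 * i + 1) / 16)
                  for i in range(8))
            for k in range(8)]
        np.testing.assert_allclose(row, expected, rtol=1e-9)


def test_epncc_zero_window_errors_not_nans():
    with pytest.raises(DegenerateInputError):
        cepstral.epncc_features(np.zeros(450))


def test_epncc_deterministic_and_amplitude_invariant(seeded_window):
    bank = cepstral.build_gammatone_bank(n_bins=226)
    a = cepstral.epncc_features(seeded_window, ensemble_size=8, seed=5,
                                bank=bank)
    b = cepstral.epncc_features(seeded_window, ensemble_size=8, seed=5,
                                bank=bank)
    np.testing.assert_array_equal(a.coeffs, b.coeffs)

    scaled = cepstral.epncc_features(7.0 * seeded_window, ensemble_size=8,
                                     seed=5, bank=bank)
    assert scaled.kept_indices == a.kept_indices
    np.testing.assert_allclose(scaled.coeffs, a.coeffs, rtol=1e-7, atol=1e-9)
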