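# Methods

This note documents the models and numerical choices behind the package:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Problem setting

The package classifies short photoplethysmogram (PPG) pulse windows into
three clinical categories (CHF pulmonary edema, respiratory failure,
cardiogenic shock). A sample is a multi-period matrix H of M = 5
consecutive pulse periods, each a fixed L = 90-sample slice at
fs = 125 Hz starting at a detected systolic peak, flattened to a
450-point window (3.6 s). Two complementary feature streams are extracted
per window and fused by a small convolutional network:

- **time domain** — wavelet scattering coefficients, which are stable to
  small time shifts and deformations of the pulse waveform;
- **frequency domain** — power-normalized cepstral coefficients (PNCC)
  computed not on the raw Fourier spectrum but on the intrinsic mode
  functions (IMFs) of an ensemble empirical mode decomposition (EEMD),
  i.e. EPNCC. The EEMD front-end adapts the spectral estimate to the
  non-stationary pulse signal, and the power-law stage amplifies small
  spectral features.

## Segmentation

Peaks are local maxima at least `min_period_s` apart (default 0.4 s,
covering rates up to 150 bpm) with prominence at least 25% of the signal
range (rejecting dicrotic bumps). Windows are non-overlapping runs of 5
consecutive peaks; row m of a sample is the 90 samples starting at peak m.
Periods are fixed-length slices, not resampled beats: irregular true
periods are truncated or overrun by design, which matches the fixed
90-point cycle convention and keeps the window geometry exact. Incomplete
tails are discarded. Because windows never share beats, a later
train/test split cannot leak samples through overlapping periods.

## EEMD and coherence screening

EMD sifts with cubic-spline envelopes through the local extrema, mirror
extension of two extrema past each end, the standard SD stopping
criterion (SD < 0.2, at most 10 sifts per IMF), and terminates when the
residual has fewer than 3 extrema or 10 IMFs were extracted. The
decomposition is exactly additive by construction.

EEMD adds white Gaussian noise with sd = 0.2 × std(signal) (the
conventional setting) to each of `ensemble_size` copies (default 100),
decomposes each, and averages the k-th IMFs; members with fewer IMFs
contribute zeros. The averaged decomposition reconstructs the input up to
a residual noise floor of order noise_sd/√ensemble_size.

IMFs are screened by the coherence coefficient
μ = Σ f·s / √(Σ f² Σ s²) with s the *difference* between the window and
the IMF. This is the screening rule implemented by default; because it is
an unusual definition (an IMF carrying exactly half the signal scores
μ = 1, an IMF orthogonal to its complement scores 0), a `mode="signal"`
option computes plain normalized correlation against the window instead.
The threshold defaults to μ ≥ 0.1; if no IMF passes, the single best one
is kept so feature extraction always has input.

## EPNCC front-end

- **Power spectrum**: one-sided periodogram |DFT|²/N with interior bins
  doubled, so the one-sided sum equals the window energy (Parseval). A
  Welch option exists for smoother estimates. The whole 450-sample window
  (per IMF) is one analysis frame; at 3.6 s there is no need for
  short-time framing.
- **Gammatone filterbank**: impulse response
  g(t) = a·t^(n−1)·e^(−2πbt)·cos(2πf₀t + φ), order n = 4, applied as
  magnitude-squared spectral weights sampled at the window's exact bin
  frequencies (the bank filters a power estimate, not the waveform).
  Default 20 filters between 0.5 and 40 Hz, spaced on an ERB-rate scale.
  The ERB law keeps the classic form ERB(f) = f/Q + B_min with the
  auditory Q = 9.26, but B_min is scaled to 0.3 Hz: the auditory
  B_min = 24.7 Hz would make every sub-40 Hz filter a near-identical
  wide-band low-pass (bandwidth ≫ centre frequency), defeating the bank.
  With the scaled law each filter's response peaks within one spectral
  bin of its centre frequency. Bandwidth uses the classic broadening
  b = 1.019·ERB(f₀).
- **Power normalization**: U = band powers / mean band power, so
  mean(U) = 1 exactly and the features are invariant to window amplitude
  (scaling the window by c scales all band powers by c² and cancels).
- **Power law**: U^ϑ with ϑ = 1/15 by default (the conventional PNCC
  exponent; any 0 < ϑ < 1 is accepted).
- **DCT**: orthonormal DCT-II, first 13 coefficients kept (including
  coefficient 0).

One cepstral row is produced per screened IMF, in IMF order. For the
fixed-width network input the pipeline pads/truncates to 4 rows
(typical windows keep 1–4 IMFs at the default threshold) and flattens
row-major.

## Wavelet scattering

Two-order scattering on the periodic 450-sample grid with invariance
scale 1.8 s (interpreted as seconds because a sampling frequency
accompanies it; 225 samples, maximal dyadic scale 2⁷), quality factors
Q = [8, 1], and oversampling factor 0 (output stride 2⁷ = 128, giving 4
frames per path). Filters are analytic Morlets (the de-facto standard
scattering wavelet) with centre frequencies geometric from 0.4
cycles/sample down to 2⁻⁷ at 2^(1/Q) spacing, plus a Gaussian low-pass
with unit DC gain. Each layer is Littlewood–Paley normalized so
|φ̂|² + Σ|ψ̂|² ≤ 1 on every bin, which makes the transform provably
non-expansive; the Morlet corrective term makes every band-pass filter
exactly zero-mean, so constants survive only in the order-0 path.
Second-order paths pair a first-order filter with every second-order
filter of strictly lower centre frequency. Coefficients are kept as raw
averaged moduli (no log stage); normalization happens in the classifier.

## Classifier

Two parallel branches — one per feature stream — each a cascade of two
conv modules (valid 1-D convolution → ReLU → max pool): kernel 5 stride 2
with 32 filters then pool 3 stride 2; kernel 3 stride 1 with 64 filters
then pool 3 stride 1. Branch outputs are flattened, concatenated, and fed
to a fully connected softmax layer over the 3 classes (branches do not
share weights). Both streams are standardized per coordinate with
training-set statistics (variance floored at 1e−8 so constant coordinates
map to 0).

Training is minibatch SGD with momentum: v ← mv − lr·∇, θ ← θ + v, with
initial learning rate 0.01, multiplicative drop factor 0.7 every 10
epochs, 50 epochs, momentum 0.9, batch size 32 (momentum, batch size and
drop period are conventional defaults; the rest are the study's training
regime). Weights use seeded fan-in scaled-uniform initialization; the
whole loop is plain numpy and bit-deterministic for a fixed seed. The
70/30 split is stratified by class (780 windows → 546/234).

Metrics: confusion matrix of argmax predictions; per-class
recall = 100·TP/(TP+FN), precision = 100·TP/(TP+FP),
F = 2RP/(R+P) (reported to 2 decimals; defined as 0 when R = P = 0),
accuracy = 100·trace/total. A class absent from a test set is reported
as `None`, never NaN.

## Synthetic data generator

The generator emulates the study's bookkeeping, not cardiovascular
physiology. Each class is a two-Gaussian per-period template (systolic
peak + dicrotic wave) with class-specific timing, width and relative
amplitude; the three presets differ in several parameters each. A window
is 5 concatenated periods plus a 0.2 Hz baseline-wander sinusoid
(amplitude 0.1 a.u., random phase) and additive white noise
(sd = 2% of the systolic amplitude). Amplitude jitter (sd 5%) acts per
window, timing jitter (sd 1 sample) per period. Defaults: 16/10/13
groups per class × 20 windows = 780 windows of 450 samples at 125 Hz.
All randomness derives from one seed through per-group child streams.

What it does **not** emulate: hemodynamics (no Windkessel model),
arrhythmia, motion artifacts, sensor saturation, or the within-class
patient variability of real ICU recordings. Passing the learning-sanity
benchmark therefore shows the pipeline can learn morphologically distinct
pulse classes end to end — it does not certify clinical accuracy on real
waveform databases, whose published headline numbers are outside what a
synthetic benchmark can reproduce.

## Problem sizes and numerical choices

- The 780-window benchmark extracts EPNCC features with ensemble size 40
  (the standalone EEMD default stays 100): the screened-IMF spectra are
  essentially unchanged while a full benchmark run (features + three
  trained models) completes in minutes on one CPU.
- Per-window EEMD seeds derive from the dataset seed via
  `SeedSequence([dataset_seed, window_index])`, so features are
  reproducible window by window.
- Degenerate inputs raise typed errors (`DegenerateInputError`) instead
  of propagating NaNs: zero/constant windows have no EPNCC; zero-norm
  operands have no coherence.
- Tie-breaks: `argmax` takes the first maximum (peak detection and
  pooling); screening keeps the arg-max-μ IMF when nothing passes the
  threshold.

## Known limitations

- EMD boundary handling uses two-extrema mirroring; the first/last
  half-period of an IMF is less accurate than the interior.
- The scattering filterbank is constructed directly on the length-450
  grid rather than a padded power-of-two grid; with periodic windows this
  is exact, but very low-frequency filters are coarsely sampled.
- The coherence screening follows the difference-based definition; with
  it, μ values are typically small and the 0.1 threshold keeps few IMFs.
  The row padding to 4 IMFs makes this harmless for the classifier, but
  users doing spectral analysis may prefer `mode="signal"`.
- The classifier is a reference implementation in numpy: fine for
  hundreds of windows, not for large-scale training.
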