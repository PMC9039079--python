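# epncc

Time–frequency feature extraction and classification for pulse (PPG)
signals: **EPNCC** — power-normalized cepstral coefficients computed on
the intrinsic mode functions of an ensemble empirical mode decomposition
(EEMD) — fused with **wavelet scattering** time-domain features and
classified by a small two-branch 1-D convolutional network.

## Who this is for

Researchers working with photoplethysmogram waveforms who want a
reproducible, dependency-light pipeline for classifying short pulse
windows into clinical categories, plus the individual building blocks
(peak segmentation, EMD/EEMD, Gammatone cepstral front-end, 1-D
scattering transform) as a library.

## The method

A sample is a matrix of M = 5 consecutive pulse periods, each a 90-sample
slice at 125 Hz starting at a systolic peak (a 450-point window). Two
feature streams are extracted:

- **Frequency domain (EPNCC).** The window is decomposed by EEMD; IMFs
  are screened by the coherence coefficient
  μ = Σ f·s / √(Σf² Σs²) (s = window − IMF). Each kept IMF passes
  through periodogram → Gammatone filterbank
  (g(t) = a·t^(n−1)·e^(−2πbt)·cos(2πf₀t+φ), ERB-spaced over 0.5–40 Hz)
  → power normalization U = P/μ[ω] (unit mean) → power law U^ϑ
  (ϑ = 1/15) → DCT-II, keeping 13 cepstral coefficients.
- **Time domain (wavelet scattering).** A two-order Morlet scattering
  transform (invariance scale 1.8 s, quality factors [8, 1], periodic
  boundary), whose coefficients |…|r∗ψ_{α1}|∗ψ_{α2}|∗φ are stable to
  translations and small deformations of the beat morphology.

Both streams are standardized with training-set statistics and fed to
parallel conv branches (conv 5/stride 2/32 filters → pool 3/2;
conv 3/1/64 → pool 3/1), concatenated into a softmax head, and trained
with SGD + momentum (lr 0.01, ×0.7 every 10 epochs, 50 epochs).
Evaluation reports the confusion matrix, per-class recall, precision,
F = 2RP/(R+P), and accuracy.

Because the clinical waveform database the method targets cannot be
redistributed, the package ships a seeded synthetic PPG generator that
reproduces the experiment's structure: 3 classes with distinct
two-Gaussian pulse morphologies, 39 record groups (16/10/13 per class)
× 20 windows = 780 samples of 450 points, split 546/234 for
training/testing.

## Worked example

```bash
python examples/05_train_and_evaluate.py
```

prints (reduced 60-window benchmark, seed 7):

```
dataset: 60 windows of 450 samples
time stream: 668 scattering coefficients; freq stream: 52 EPNCC coefficients
train/test: 42/18
confusion (rows = true):
[[7 0 0]
 [0 5 0]
 [0 0 6]]
  chf_pulmonary_edema    recall 100.00%  precision 100.00%  F 100.00%
  respiratory_failure    recall 100.00%  precision 100.00%  F 100.00%
  cardiogenic_shock      recall 100.00%  precision 100.00%  F 100.00%
accuracy: 100.00%
```

The confusion matrix rows are the true classes; recall/precision/F are
per class in percent and accuracy is correct predictions over the 18
held-out windows. The other examples demonstrate the stages one at a
time — e.g. `examples/02_eemd_screening.py`:

```
6 IMFs from a 450-sample window
  IMF 1: 297 zero crossings, mu = +0.011
  ...
  IMF 5:   9 zero crossings, mu = +0.585
kept IMFs (0-based indices): [2, 3, 4, 5]
ensemble reconstruction error: 1.43e-02 (shrinks as the ensemble grows)
```

and `examples/04_scattering_features.py`, which shows the scattering
features moving by <3% under shifts up to 10% of the invariance scale.

A thin CLI mirrors the library (`epncc simulate | segment | eemd |
epncc | scatter | featurize | train | evaluate`); run `epncc --help`.

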