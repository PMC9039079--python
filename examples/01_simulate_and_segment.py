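"""Generate a synthetic PPG record and segment it into 5-period samples.

Builds a ~60 s CHF-like pulse record at 125 Hz, detects systolic peaks,
and assembles non-overlapping windows of 5 x 90-sample periods. The
printed numbers show the detected beat spacing and the sample geometry
every downstream stage assumes (450 points per window).
"""

import numpy as np

from epncc import segmentation, synthetic

record = synthetic.generate_record(
    synthetic.CHF_PULMONARY_EDEMA, n_periods=83,
    rng=np.random.default_rng(42))
print(f"record: {record.size} samples ({record.size / 125:.1f} s at 125 Hz)")

peaks = segmentation.detect_peaks(record, fs=125.0)
spacing = np.diff(peaks)
print(f"peaks: {peaks.size}, median spacing {np.median(spacing):.0f} samples "
      f"(~{60 * 125 / np.median(spacing):.0f} bpm)")

windows = segmentation.build_windows(record, peaks, M=5, L=90)
print(f"windows: {len(windows)}, each {windows[0].values.shape[0]} periods "
      f"x {windows[0].values.shape[1]} samples = "
      f"{windows[0].flatten().size} points")
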