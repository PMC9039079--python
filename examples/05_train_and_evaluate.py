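"""Train the fused time-frequency classifier on a reduced benchmark.

Uses a smaller dataset than the full 780-window benchmark (4/3/3 groups
x 6 windows = 60 windows) so the example runs in well under a minute;
`scripts/acceptance.py` runs the full-size version. Prints the per-class
recall/precision/F-measure and overall accuracy on the held-out 30%.
"""

from epncc import pipeline, synthetic
from epncc.network import TrainConfig

dataset = synthetic.generate_dataset((4, 3, 3), 6, seed=7)
print(f"dataset: {dataset.n_windows} windows of {dataset.window_len} samples")

features = pipeline.extract_features(dataset)
print(f"time stream: {features.time.shape[1]} scattering coefficients; "
      f"freq stream: {features.freq.shape[1]} EPNCC coefficients")

result = pipeline.run_benchmark(
    features, train_config=TrainConfig(seed=7, max_epochs=30))
report = result.report
print(f"train/test: {report.extra['n_train']}/{report.extra['n_test']}")
print("confusion (rows = true):")
print(report.confusion)
for name, r, p, f in zip(report.class_names, report.recall,
                         report.precision, report.f_score):
    print(f"  {name:22s} recall {r:6.2f}%  precision {p:6.2f}%  F {f:6.2f}%")
print(f"accuracy: {report.accuracy:.2f}%")
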