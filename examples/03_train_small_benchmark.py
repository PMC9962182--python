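"""Train the ST-GCN classifier on a reduced synthetic benchmark.

Uses 4 subjects and a 40-epoch budget so the example finishes in about
three minutes on one CPU; the full protocol (17 subjects, early stopping
up to 1000 epochs) is what `scripts/acceptance.py` and the CLI
`fallgcn train` run. Prints test accuracy and the per-class table; fall
classes (ids 1-5) are the ones that matter for an alarm system.
"""

import fallgcn as fg

sequences = fg.generate_dataset(fg.SyntheticConfig(subjects=4, seed=0))
windows = fg.segment_many(sequences, window_sec=2.0, drop_background=True)

model_config = fg.ModelConfig(
    partition=fg.PartitionConfig("spatial-configuration", max_distance=1)
)
train_config = fg.TrainConfig(max_epochs=40, patience=40, seed=0, verbose=True)
result = fg.run_experiment(windows, model_config, train_config, fg.SplitSpec(seed=0))

print(f"\ntest accuracy: {result.report.accuracy:.2f} %")
print(f"macro F1:      {result.report.macro_f1:.2f} %")
print(result.report.per_class.round(2))
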