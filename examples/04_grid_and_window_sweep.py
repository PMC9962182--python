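"""Hyperparameter grid (partition strategy x MD) and window-size sweep.

Reduced-scale version of the two protocol experiments: the 3 x 2 grid of
partition strategy against neighbourhood radius MD, and the accuracy /
precision / recall / F1 table for 1, 2 and 3 s windows at 50% overlap.
Run at this scale the numbers are noisy; the point is the harness.
"""

import fallgcn as fg

sequences = fg.generate_dataset(fg.SyntheticConfig(subjects=3, seed=0))
windows = fg.segment_many(sequences, window_sec=2.0, drop_background=True)

model_config = fg.ModelConfig()
train_config = fg.TrainConfig(max_epochs=3, patience=3, seed=0)
split = fg.SplitSpec(seed=0)

grid = fg.grid_search(windows, model_config, train_config, split)
print("accuracy (%) per partition strategy and MD:")
print(grid.table.round(2))
print(f"best cell: {grid.best[0]}, MD={grid.best[1]}")

sweep = fg.window_sweep(sequences, model_config, train_config, split)
print("\nmetrics (%) per window size:")
print(sweep.round(2))
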