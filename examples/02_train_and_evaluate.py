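"""Train a small diffusivity regressor and check it on held-out data.

Uses a coarse label grid and a short schedule so the whole script runs
in about two minutes; the reduced-scale benchmark recipe lives in
``blurmap.train_scaled_model`` and the full-scale recipe in the
``TrainConfig``/``build_training_dataset`` defaults.
"""

import numpy as np

import blurmap as bm
from blurmap.nn import ModelConfig, TrainConfig, build_model, train

config = bm.SimConfig()
labels = bm.default_label_grid(step=0.5)  # 13 labels, 0-6 µm²/s
combos = bm.default_augmentation_grid(config)

print(f"building {len(labels)} labels x {len(combos)} combos x 4 stacks ...")
dataset = bm.build_training_dataset(config, labels, combos, 4, seed=11,
                                    n_ch=40, mix_within_stack=True)
model = build_model(ModelConfig(), seed=1)
print(f"model: widths {model.config.widths}, {model.n_parameters} parameters")

model, log = train(model, dataset,
                   TrainConfig(epochs=10, lr_drop_every=5, seed=2),
                   verbose=True)

print("\nheld-out single-stack evaluation (200 stacks per D):")
rep = bm.heldout_precision(model, seed=99, D_list=(1.0, 2.0, 3.0, 4.0),
                           n_eval=200)
print(rep.to_string(index=False))
print("\nmean_E should track true_D; sd_pct_error is the single-stack "
      "precision\n(the full recipe reaches ~12%; this quick run is coarser).")
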