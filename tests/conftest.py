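"""Shared fixtures.

Two trained models are provided at session scope:

``tiny_model``
    A quickly trained low-capacity regressor for smoke/contract tests
    where only qualitative behaviour (ordering, plumbing) matters.
``scaled_model``
    The reduced-scale training recipe (25 labels, 4 augmentation
    combos, 50 stacks each, 20 epochs) used for the quantitative
    evaluation tests.  Training takes a few minutes, so the checkpoint
    is cached under scratch/ keyed by the recipe seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

import blurmap as bm
from blurmap.nn import ModelConfig, TrainConfig, build_model, train, \
    save_checkpoint, load_checkpoint

SCALED_SEED = 1
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


@pytest.fixture(scope="session")
def sim_config() -> bm.SimConfig:
    return bm.SimConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model(sim_config):
    """Low-capacity model trained in ~1 min; qualitative use only."""
    SCRATCH.mkdir(exist_ok=True)
    path = SCRATCH / "tiny_model_seed7.ckpt.npz"
    if path.exists():
        return load_checkpoint(path)
    labels = bm.default_label_grid(step=0.5)  # 13 labels
    ds = bm.build_training_dataset(sim_config, labels, [(60.0, 5.0), (120.0, 15.0)],
                                   40, seed=7, n_ch=40)
    model = build_model(ModelConfig(), seed=7)
    model, _ = train(model, ds, TrainConfig(epochs=8, lr_drop_every=4, seed=7))
    save_checkpoint(model, path)
    return model


@pytest.fixture(scope="session")
def scaled_model():
    """The reduced-scale recipe the quantitative tests evaluate."""
    SCRATCH.mkdir(exist_ok=True)
    path = SCRATCH / f"scaled_model_seed{SCALED_SEED}.ckpt.npz"
    if path.exists():
        return load_checkpoint(path)
    model, _, _ = bm.train_scaled_model(seed=SCALED_SEED)
    save_checkpoint(model, path)
    return model
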