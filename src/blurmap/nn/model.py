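"""The diffusivity regressor: a shallow residual CNN on image stacks.

The network maps a stack of ``n_ch`` uncorrelated 7×7 single-molecule
images (stacked along the channel axis) to a single diffusion
coefficient.  An individual blurred image does not determine D — the
same D produces diverse trajectories — so the stack is the natural input
unit: the convolutional blocks see all channels jointly and the head
regresses one scalar.

Architecture (config-exposed): a stack of conv(3×3) + batchnorm + Swish
blocks with identity residual shortcuts where widths match, global
average pooling, and a fully connected regression head.  Kept shallow
(default widths 32-32-64-64, < 10⁵ parameters) to avoid overfitting the
simulated data.  Training is SGD with momentum on the MSE loss against
the D labels, with a step learning-rate schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .layers import (ConvBlock, Dense, GlobalAvgPool, Sequential, SGD, mse_loss)

__all__ = ["ModelConfig", "TrainConfig", "TrainingLog", "DiffusivityCNN",
           "build_model", "train", "predict_stack", "predict_stacks",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    n_ch: int = 40
    widths: tuple[int, ...] = (32, 32, 64, 64)
    kernel_size: int = 3
    norm_scale: float = 100.0  # global count scale applied after median subtraction

    def __post_init__(self):
        if self.kernel_size != 3:
            raise ValueError("only 3x3 kernels are supported")
        if self.n_ch < 1 or not self.widths:
            raise ValueError("invalid model config")


@dataclass(frozen=True)
class TrainConfig:
    """Full-scale defaults: 60 epochs, batch 128, lr 0.003 divided by 10
    every 25 epochs, SGD momentum 0.9, MSE loss on the physical D scale."""

    epochs: int = 60
    batch_size: int = 128
    initial_lr: float = 0.003
    momentum: float = 0.9
    lr_drop_every: int = 25
    lr_drop_factor: float = 10.0
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.initial_lr <= 0:
            raise ValueError("invalid training config")
        if self.lr_drop_every > self.epochs:
            raise ValueError("lr schedule step must be <= epochs")

    def lr_at(self, epoch: int) -> float:
        return self.initial_lr / self.lr_drop_factor ** (epoch // self.lr_drop_every)


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


class DiffusivityCNN:
    """Shallow residual CNN regressing D (µm²/s) from an image stack."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 dtype=np.float32):
        self.config = config
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        layers = []
        c_prev = config.n_ch
        for w in config.widths:
            layers.append(ConvBlock(c_prev, w, rng, dtype=self.dtype))
            c_prev = w
        layers.append(GlobalAvgPool())
        layers.append(Dense(c_prev, 1, rng, dtype=self.dtype))
        self.net = Sequential(layers)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.net.params)

    def normalize(self, stacks: np.ndarray) -> np.ndarray:
        """Per-image median subtraction then a fixed global count scale.

        Removes the additive background level per channel image while
        keeping the absolute signal scale (brightness) visible to the
        network; the scale constant travels with the checkpoint.
        """
        x = np.asarray(stacks, dtype=self.dtype)
        med = np.median(x, axis=(-2, -1), keepdims=True)
        return ((x - med) / np.asarray(self.config.norm_scale,
                                       dtype=self.dtype)).astype(self.dtype)

    def forward_raw(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.config.n_ch:
            raise ValueError(f"expected {self.config.n_ch} channels, got {x.shape[1]}")
        return self.net.forward(x, train)

    def predict(self, stacks: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """D predictions for (N, n_ch, r, r) stacks (eval mode, unclamped)."""
        stacks = np.asarray(stacks)
        single = stacks.ndim == 3
        if single:
            stacks = stacks[None]
        out = np.empty(len(stacks))
        for i in range(0, len(stacks), batch_size):
            x = self.normalize(stacks[i:i + batch_size])
            out[i:i + batch_size] = self.forward_raw(x, train=False)[:, 0]
        return out[0] if single else out


def build_model(config: ModelConfig | None = None, seed: int = 0) -> DiffusivityCNN:
    return DiffusivityCNN(config or ModelConfig(), seed=seed)


def _holdout_split(labels: np.ndarray, val_fraction: float, rng):
    """Stratified per-label holdout indices (val_idx boolean mask)."""
    val = np.zeros(len(labels), dtype=bool)
    if val_fraction <= 0:
        return val
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_val = max(1, int(round(val_fraction * len(idx)))) if len(idx) > 1 else 0
        val[rng.permutation(idx)[:n_val]] = True
    return val


def train(model: DiffusivityCNN, dataset, config: TrainConfig | None = None,
          verbose: bool = False):
    """Train on a :class:`~blurmap.sim.TrainingDataset`; returns (model, log).

    Raises ``RuntimeError`` if the loss diverges to NaN/inf.
    """
    config = config or TrainConfig()
    if len(dataset.stacks) == 0:
        raise ValueError("dataset is empty")
    labels = np.asarray(dataset.labels, dtype=float)
    if labels.min() < 0 or labels.max() > 6.0:
        raise ValueError("labels must lie within [0, 6] µm²/s")
    rng = np.random.default_rng(config.seed)
    val_mask = _holdout_split(labels, config.val_fraction, rng)
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)
    x_all = model.normalize(dataset.stacks)
    y_all = labels[:, None].astype(x_all.dtype)
    log = TrainingLog()
    opt = SGD(model.net.params, config.initial_lr, config.momentum)
    B = config.batch_size
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(tr_idx)
        total, nb = 0.0, 0
        for i in range(0, len(order), B):
            sel = order[i:i + B]
            pred = model.forward_raw(x_all[sel], train=True)
            loss, dpred = mse_loss(pred, y_all[sel])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss})")
            model.net.backward(dpred)
            opt.step(model.net.grads)
            total += loss
            nb += 1
        log.train_loss.append(total / max(nb, 1))
        log.lr.append(opt.lr)
        if len(va_idx):
            pv = np.concatenate([
                model.forward_raw(x_all[va_idx[j:j + 512]], train=False)[:, 0]
                for j in range(0, len(va_idx), 512)])
            log.val_loss.append(float(np.mean((pv - labels[va_idx]) ** 2)))
        if verbose:
            vl = log.val_loss[-1] if log.val_loss else float("nan")
            print(f"epoch {epoch + 1:3d}/{config.epochs}  lr {opt.lr:.2e}  "
                  f"train {log.train_loss[-1]:.4f}  val {vl:.4f}")
    return model, log


def predict_stack(model: DiffusivityCNN, stack) -> float:
    """Scalar D for one stack (deterministic; may be negative — clamping
    to zero happens only at the mapping stage)."""
    images = stack.images if hasattr(stack, "images") else np.asarray(stack)
    if images.ndim != 3 or images.shape[0] != model.config.n_ch:
        raise ValueError(f"stack must be ({model.config.n_ch}, r, r)")
    return float(model.predict(images))


def predict_stacks(model: DiffusivityCNN, stacks: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(stacks))


def save_checkpoint(model: DiffusivityCNN, path, train_seed: int | None = None,
                    log: TrainingLog | None = None) -> None:
    """Single-file .npz archive: weights + config + normalization + seed."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.net.params)}
    bn_state = []
    for layer in model.net.layers:
        if isinstance(layer, ConvBlock):
            bn_state.append(layer.bn.running_mean)
            bn_state.append(layer.bn.running_var)
    for i, a in enumerate(bn_state):
        arrays[f"bnstat_{i}"] = a
    meta = {"model_config": asdict(model.config),
            "train_seed": train_seed,
            "log": asdict(log) if log is not None else None}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> DiffusivityCNN:
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        cfg = dict(meta["model_config"])
        cfg["widths"] = tuple(cfg["widths"])
        model = DiffusivityCNN(ModelConfig(**cfg), seed=0)
        for i, p in enumerate(model.net.params):
            p[...] = f[f"param_{i}"]
        i = 0
        for layer in model.net.layers:
            if isinstance(layer, ConvBlock):
                layer.bn.running_mean[...] = f[f"bnstat_{i}"]
                layer.bn.running_var[...] = f[f"bnstat_{i + 1}"]
                i += 2
    return model
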