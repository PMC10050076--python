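"""Minimal CPU neural-network layers (forward + backward) in numpy.

Only what the diffusivity regressor needs: 3×3 same-padding convolution
(im2col into one BLAS matmul), batch normalization, Swish activation,
global average pooling, a dense head, and SGD with momentum.  Inputs are
NCHW arrays; spatial sizes here are tiny (7×7), so this is fast on one
CPU core.  Layers default to float32 (ample for this regression task);
pass ``dtype=np.float64`` e.g. for finite-difference gradient checks.

Every layer exposes ``forward(x, train)`` and ``backward(grad)``;
parameters and their gradients are flat lists aligned by index.
Gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "BatchNorm2d", "Swish", "ConvBlock",
           "GlobalAvgPool", "Dense", "Sequential", "SGD", "mse_loss"]


class Layer:
    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


DTYPE = np.float32  # training precision; plenty for this regression task


class Conv3x3(Layer):
    """3×3 convolution, stride 1, zero same-padding (im2col + one matmul)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=DTYPE):
        self.dtype = np.dtype(dtype)
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(3, 3, c_in, c_out)).astype(self.dtype)
        self.b = np.zeros(c_out, dtype=self.dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, xp: np.ndarray, H: int, W: int) -> np.ndarray:
        # (N, C, H+2, W+2) -> (N*H*W, 3*3*C), patch layout (dy, dx, c)
        N = xp.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # win: (N, C, H, W, 3, 3) -> (N, H, W, 3, 3, C)
        cols = win.transpose(0, 2, 3, 4, 5, 1).reshape(N * H * W, 9 * self.c_in)
        return np.ascontiguousarray(cols, dtype=self.dtype)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        xp = np.pad(np.asarray(x, dtype=self.dtype),
                    ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = self._im2col(xp, H, W)
        if train:
            self._cols, self._dims = cols, (N, H, W)
        out = cols @ self.W.reshape(9 * self.c_in, self.c_out) + self.b
        return out.reshape(N, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, H, W = self._dims
        g = np.ascontiguousarray(
            grad.transpose(0, 2, 3, 1).reshape(N * H * W, self.c_out),
            dtype=self.dtype)
        self.dW[:] = (self._cols.T @ g).reshape(self.W.shape)
        self.db[:] = g.sum(axis=0)
        dcols = g @ self.W.reshape(9 * self.c_in, self.c_out).T
        dcols = dcols.reshape(N, H, W, 3, 3, self.c_in)
        dxp = np.zeros((N, self.c_in, H + 2, W + 2), dtype=self.dtype)
        for dy in range(3):  # col2im scatter-add over the 9 offsets
            for dx in range(3):
                dxp[:, :, dy:dy + H, dx:dx + W] += \
                    dcols[:, :, :, dy, dx, :].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=DTYPE):
        self.dtype = np.dtype(dtype)
        self.gamma = np.ones(c, dtype=self.dtype)
        self.beta = np.zeros(c, dtype=self.dtype)
        self.dgamma = np.zeros(c, dtype=self.dtype)
        self.dbeta = np.zeros(c, dtype=self.dtype)
        self.running_mean = np.zeros(c, dtype=self.dtype)
        self.running_var = np.ones(c, dtype=self.dtype)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._cache
        axes = (0, 2, 3)
        self.dgamma[:] = (grad * xhat).sum(axis=axes)
        self.dbeta[:] = grad.sum(axis=axes)
        gg = self.gamma[None, :, None, None] * grad
        return inv[None, :, None, None] * (
            gg - gg.mean(axis=axes, keepdims=True)
            - xhat * (gg * xhat).mean(axis=axes, keepdims=True))


class Swish(Layer):
    """x · sigmoid(x) — smooth, non-monotone near 0; suits regression."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        s = 1.0 / (1.0 + np.exp(-x))
        self._cache = (x, s)
        return x * s

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, s = self._cache
        return grad * (s * (1.0 + x * (1.0 - s)))


class ConvBlock(Layer):
    """conv(3×3) → batchnorm → Swish, with an identity shortcut when the
    channel widths match (ResNet-style residual connection)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 residual: bool = True, dtype=DTYPE):
        self.conv = Conv3x3(c_in, c_out, rng, dtype=dtype)
        self.bn = BatchNorm2d(c_out, dtype=dtype)
        self.act = Swish()
        self.residual = residual and (c_in == c_out)

    @property
    def params(self):
        return self.conv.params + self.bn.params

    @property
    def grads(self):
        return self.conv.grads + self.bn.grads

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)
        return y + x if self.residual else y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = self.conv.backward(self.bn.backward(self.act.backward(grad)))
        return dx + grad if self.residual else dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (H * W), self._shape).copy()


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=DTYPE):
        self.dtype = np.dtype(dtype)
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in),
                            size=(c_in, c_out)).astype(self.dtype)
        self.b = np.zeros(c_out, dtype=self.dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = np.asarray(x, dtype=self.dtype)
        return self._x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
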