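"""Minimal numpy neural-network layers with manual backpropagation.

This module provides exactly the pieces the residual convolutional
regressor needs — 1-D same-padded convolution, batch normalization, ReLU,
valid max-pooling, flatten, inverted dropout, dense layers and the Adam
optimizer — with float32 arithmetic throughout. Layers cache forward
activations and are intended for the usual sequential single-use-per-pass
pattern.

Freezing semantics: a layer whose ``trainable`` flag is False is excluded
from optimizer updates, and a frozen :class:`BatchNorm` additionally runs
in inference mode (running statistics, no updates) even during training,
so frozen feature extractors stay bitwise stable under fine-tuning.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv1DSame",
    "BatchNorm",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dropout",
    "Dense",
    "ResidualBlock",
    "Adam",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    """Scaled-uniform initialization with Glorot fan-based bounds."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    trainable: bool = True

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. BN running statistics)."""
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1DSame(Layer):
    """1-D convolution over (batch, length, channels) with 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.W = Param(glorot_uniform(rng, fan_in, fan_out, (kernel * c_in, c_out)))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training, rng=None):
        B, L, C = x.shape
        k = self.kernel
        pl = k // 2
        pr = k - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # (B, L, C, k) -> (B, L, k, C) -> (B*L, k*C)
        win = sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
        cols = np.ascontiguousarray(win).reshape(B * L, k * C)
        self._cols = cols
        self._in_shape = (B, L, C)
        y = cols @ self.W.value + self.b.value
        return y.reshape(B, L, self.c_out)

    def backward(self, dy):
        B, L, C = self._in_shape
        k = self.kernel
        pl = k // 2
        dy_flat = dy.reshape(B * L, self.c_out)
        self.W.grad += self._cols.T @ dy_flat
        self.b.grad += dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.W.value.T).reshape(B, L, k, C)
        dxp = np.zeros((B, L + k - 1, C), dtype=np.float32)
        for j in range(k):
            dxp[:, j : j + L, :] += dcols[:, :, j, :]
        self._cols = None
        return dxp[:, pl : pl + L, :]


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (channel/feature).

    Works for both convolutional (B, L, C) and dense (B, F) activations.
    Running statistics use exponential averaging with the given momentum.
    """

    def __init__(self, width: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(width, dtype=np.float32))
        self.beta = Param(np.zeros(width, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(width, dtype=np.float32)
        self.running_var = np.ones(width, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training and self.trainable:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[:] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[:] = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = ("train", xhat, inv, axes)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv
            self._cache = ("eval", None, inv, axes)
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, dy):
        mode, xhat, inv, axes = self._cache
        if mode == "eval":
            # Frozen/inference normalization is an affine map per feature.
            return (dy * self.gamma.value * inv).astype(np.float32)
        m = np.prod([dy.shape[a] for a in axes])
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        dx = (self.gamma.value * inv / m) * (m * dy - dbeta - xhat * dgamma)
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, training, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool1D(Layer):
    """Valid max-pooling over the length axis: pool size p, stride w."""

    def __init__(self, pool: int, stride: int):
        self.pool, self.stride = pool, stride

    @staticmethod
    def out_length(L: int, pool: int, stride: int) -> int:
        return (L - pool) // stride + 1

    def forward(self, x, training, rng=None):
        B, L, C = x.shape
        M = self.out_length(L, self.pool, self.stride)
        starts = np.arange(M) * self.stride
        idx = starts[:, None] + np.arange(self.pool)
        win = x[:, idx, :]  # (B, M, p, C)
        amax = win.argmax(axis=2)
        self._cache = (x.shape, starts, amax)
        return win.max(axis=2)

    def backward(self, dy):
        (B, L, C), starts, amax = self._cache
        dx = np.zeros((B, L, C), dtype=np.float32)
        abs_pos = starts[None, :, None] + amax  # (B, M, C)
        b_idx = np.arange(B)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        np.add.at(dx, (b_idx, abs_pos, c_idx), dy)
        self._cache = None
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, d_in, d_out, (d_in, d_out)))
        self.b = Param(np.zeros(d_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        self._x = None
        return dy @ self.W.value.T


class ResidualBlock(Layer):
    """Conv–BN–ReLU–Conv–BN with identity skip, then ReLU.

    Channel width is preserved so the skip connection is a plain addition.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv1DSame(channels, channels, kernel, rng)
        self.bn1 = BatchNorm(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1DSame(channels, channels, kernel, rng)
        self.bn2 = BatchNorm(channels)
        self.relu_out = ReLU()
        self._sub = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]

    @property
    def trainable(self):
        return self.conv1.trainable

    @trainable.setter
    def trainable(self, flag: bool):
        for layer in self._sub + [self.relu_out]:
            layer.trainable = flag

    def params(self):
        out = []
        for layer in self._sub:
            out.extend(layer.params())
        return out

    def buffers(self):
        out = []
        for layer in self._sub:
            out.extend(layer.buffers())
        return out

    def forward(self, x, training, rng=None):
        h = x
        for layer in self._sub:
            h = layer.forward(h, training, rng)
        return self.relu_out.forward(h + x, training, rng)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dh = d
        for layer in reversed(self._sub):
            dh = layer.backward(dh)
        return dh + d


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
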