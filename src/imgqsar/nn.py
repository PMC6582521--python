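"""A compact NumPy neural-network engine.

Implements exactly the layer vocabulary the package's architectures need —
dense, convolutional, pooling, batch-norm, dropout — with explicit
forward/backward passes and stochastic gradient descent with Nesterov
momentum. Convolutions use im2col so both passes reduce to matrix products.

Parameters are held as ``Param`` objects (value + gradient + trainable flag);
a frozen layer participates in the forward pass but accumulates no gradient
and is skipped by the optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable


class Layer:
    """Base layer: forward caches what backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def freeze(self) -> None:
        for p in self.params():
            p.trainable = False

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


def _he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Param(_he_normal(rng, (in_dim, out_dim), in_dim))
        self.b = Param(np.zeros(out_dim))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        if self.W.trainable:
            self.W.grad += self._x.T @ grad
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability {p} outside [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho, Wo, C, kh, kw) window view (no copy)."""
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride].transpose(0, 2, 3, 1, 4, 5)


class Conv2d(Layer):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
    ):
        fan_in = in_ch * kernel * kernel
        self.W = Param(_he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.b = Param(np.zeros(out_ch)) if bias else None
        self.stride, self.pad, self.kernel = stride, pad, kernel

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train):
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp_shape = x.shape
        cols = _im2col(x, k, k, s)
        n, ho, wo = cols.shape[:3]
        self._cols = cols.reshape(n * ho * wo, -1)
        out = self._cols @ self.W.value.reshape(self.W.value.shape[0], -1).T
        if self.b is not None:
            out += self.b.value
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.pad
        n, f, ho, wo = grad.shape
        gflat = grad.transpose(0, 2, 3, 1).reshape(-1, f)
        if self.W.trainable:
            self.W.grad += (gflat.T @ self._cols).reshape(self.W.value.shape)
            if self.b is not None:
                self.b.grad += gflat.sum(axis=0)
        dcols = (gflat @ self.W.value.reshape(f, -1)).reshape(n, ho, wo, -1, k, k)
        dx = np.zeros(self._xp_shape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, train):
        k, s = self.kernel, self.stride
        if self.pad:
            p = self.pad
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        self._x_shape = x.shape
        cols = _im2col(x, k, k, s)  # (N, Ho, Wo, C, k, k)
        n, ho, wo, c = cols.shape[:4]
        flat = cols.reshape(n, ho, wo, c, k * k)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        k, s = self.kernel, self.stride
        n, c, ho, wo = grad.shape
        dwin = np.zeros((n, ho, wo, c, k * k))
        np.put_along_axis(
            dwin,
            self._argmax[..., None],
            grad.transpose(0, 2, 3, 1)[..., None],
            axis=-1,
        )
        dwin = dwin.reshape(n, ho, wo, c, k, k)
        dx = np.zeros(self._x_shape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + ho * s : s, j : j + wo * s : s] += dwin[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if self.pad:
            p = self.pad
            dx = dx[:, :, p:-p, p:-p]
        return dx


class AvgPool2d(Layer):
    """Non-overlapping average pooling (kernel == stride, dims divisible)."""

    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x, train):
        k = self.kernel
        n, c, h, w = x.shape
        self._x_shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, grad):
        k = self.kernel
        dx = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output grid (framework-style bin edges)."""

    def __init__(self, out_h: int, out_w: int):
        self.out_h, self.out_w = out_h, out_w

    def _edges(self, size: int, out: int):
        starts = [(i * size) // out for i in range(out)]
        ends = [-(-((i + 1) * size) // out) for i in range(out)]
        return starts, ends

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        hs, he = self._edges(h, self.out_h)
        ws, we = self._edges(w, self.out_w)
        self._bins = (hs, he, ws, we)
        out = np.empty((n, c, self.out_h, self.out_w))
        for i in range(self.out_h):
            for j in range(self.out_w):
                out[:, :, i, j] = x[:, :, hs[i] : he[i], ws[j] : we[j]].mean(axis=(2, 3))
        return out

    def backward(self, grad):
        hs, he, ws, we = self._bins
        dx = np.zeros(self._x_shape)
        for i in range(self.out_h):
            for j in range(self.out_w):
                area = (he[i] - hs[i]) * (we[j] - ws[j])
                dx[:, :, hs[i] : he[i], ws[j] : we[j]] += (
                    grad[:, :, i, j][:, :, None, None] / area
                )
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_ch))
        self.beta = Param(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train and self.gamma.trainable:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._batch_stats = train and self.gamma.trainable
        return (
            self.gamma.value[None, :, None, None] * self._xhat
            + self.beta.value[None, :, None, None]
        )

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        if self.gamma.trainable:
            self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
            self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not self._batch_stats:
            return g / std[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3).reshape(1, -1, 1, 1)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return (g - sum_g / m - xhat * sum_gx / m) / std[None, :, None, None]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Residual(Layer):
    """y = F(x) + shortcut(x), with ReLU applied after the sum."""

    def __init__(self, branch: Sequential, shortcut: Sequential | None = None):
        self.branch = branch
        self.shortcut = shortcut
        self.relu = ReLU()

    def params(self):
        ps = self.branch.params()
        if self.shortcut is not None:
            ps = ps + self.shortcut.params()
        return ps

    def forward(self, x, train):
        identity = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu.forward(self.branch.forward(x, train) + identity, train)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        dx = self.branch.backward(grad)
        if self.shortcut is None:
            return dx + grad
        return dx + self.shortcut.backward(grad)


class Concat(Layer):
    """Channel-wise concatenation of the input with a branch output."""

    def __init__(self, branch: Sequential):
        self.branch = branch

    def params(self):
        return self.branch.params()

    def forward(self, x, train):
        self._in_ch = x.shape[1]
        return np.concatenate([x, self.branch.forward(x, train)], axis=1)

    def backward(self, grad):
        dx_branch = self.branch.backward(grad[:, self._in_ch :])
        return grad[:, : self._in_ch] + dx_branch


class SGDNesterov:
    """SGD with Nesterov momentum (framework-standard update form)."""

    def __init__(self, params: list[Param], momentum: float = 0.9):
        self.params = [p for p in params if p.trainable]
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float) -> None:
        mu = self.momentum
        for p, v in zip(self.params, self.velocity):
            v *= mu
            v += p.grad
            p.value -= lr * (p.grad + mu * v)


def get_state(layer: Layer) -> list[np.ndarray]:
    """Snapshot all parameter values (used for best-epoch checkpointing)."""
    return [p.value.copy() for p in layer.params()]


def set_state(layer: Layer, state: list[np.ndarray]) -> None:
    for p, v in zip(layer.params(), state):
        p.value[...] = v
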