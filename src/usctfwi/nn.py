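"""Minimal CPU convolutional-network engine.

A compact layer library (forward + hand-written backward passes, Adam)
sized for the small signal-to-signal regression networks this package
trains: a 2D U-Net over shot-gather windows and a five-stage 1D CNN over
single traces. Convolutions are evaluated as im2col matrix products;
everything is plain numpy and deterministic for a fixed seed.

Not a general autograd: each layer implements ``forward(x)`` and
``backward(dy)`` with cached activations, and ``params()`` yields
(value, grad) pairs for the optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: float32 keeps the matrix products fast on CPU; switch to float64 for
#: high-precision gradient verification.
DEFAULT_DTYPE = np.float32


class Layer:
    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value, dtype=None):
        self.value = np.asarray(value, dtype=dtype or DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.value)


def _he_init(rng, shape, fan_in):
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2d(Layer):
    """Same-padded 2D convolution, stride 1, square kernel."""

    def __init__(self, c_in, c_out, k, rng):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he_init(rng, (c_in * k * k, c_out), c_in * k * k))
        self.bias = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.bias]

    def forward(self, x, train=True):
        # x: (N, C, H, W)
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N, H, W, C*k*k)
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, -1)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.w.value + self.bias.value
        return out.transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w = self._xshape
        dyt = dy.transpose(0, 2, 3, 1)  # (N,H,W,Cout)
        self.w.grad += self._cols.reshape(-1, self._cols.shape[-1]).T @ dyt.reshape(
            -1, self.c_out
        )
        self.bias.grad += dyt.reshape(-1, self.c_out).sum(axis=0)
        dcols = dyt @ self.w.value.T  # (N,H,W,C*k*k)
        dcols = dcols.reshape(n, h, w, c, self.k, self.k).transpose(0, 3, 1, 2, 4, 5)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for ki in range(self.k):
            for kj in range(self.k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj]
        return dxp[:, :, p:p + h, p:p + w]


class Conv1d(Layer):
    """Same-padded 1D convolution, stride 1."""

    def __init__(self, c_in, c_out, k, rng):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he_init(rng, (c_in * k, c_out), c_in * k))
        self.bias = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.bias]

    def forward(self, x, train=True):
        # x: (N, C, T)
        n, c, t = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = sliding_window_view(xp, self.k, axis=2)  # (N,C,T,k)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, t, -1)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.w.value + self.bias.value
        return out.transpose(0, 2, 1)

    def backward(self, dy):
        n, c, t = self._xshape
        dyt = dy.transpose(0, 2, 1)  # (N,T,Cout)
        self.w.grad += self._cols.reshape(-1, c * self.k).T @ dyt.reshape(-1, self.c_out)
        self.bias.grad += dyt.reshape(-1, self.c_out).sum(axis=0)
        dcols = (dyt @ self.w.value.T).reshape(n, t, c, self.k).transpose(0, 2, 1, 3)
        p = self.k // 2
        dxp = np.zeros((n, c, t + 2 * p), dtype=dy.dtype)
        for ki in range(self.k):
            dxp[:, :, ki:ki + t] += dcols[:, :, :, ki]
        return dxp[:, :, p:p + t]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class PReLU(Layer):
    """Parametric ReLU with one learnable slope per channel (axis 1)."""

    def __init__(self, n_channels, init=0.25):
        self.alpha = Param(np.full(n_channels, init))

    def params(self):
        return [self.alpha]

    def forward(self, x, train=True):
        self._x = x
        shape = (1, -1) + (1,) * (x.ndim - 2)
        a = self.alpha.value.reshape(shape)
        return np.where(x > 0, x, a * x)

    def backward(self, dy):
        x = self._x
        neg = x <= 0
        axes = (0,) + tuple(range(2, x.ndim))
        self.alpha.grad += (dy * x * neg).sum(axis=axes)
        shape = (1, -1) + (1,) * (x.ndim - 2)
        a = self.alpha.value.reshape(shape)
        return dy * np.where(neg, a, 1.0)


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (1)."""

    def __init__(self, n_channels, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._axes, self._shape = axes, shape
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu.reshape(shape)) / self._std.reshape(shape)
        self._m = x.size / x.shape[1]
        return self.gamma.value.reshape(shape) * self._xhat + self.beta.value.reshape(shape)

    def backward(self, dy):
        axes, shape = self._axes, self._shape
        xhat, std, m = self._xhat, self._std, self._m
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = dy * g
        return (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        ) / std.reshape(shape)


class MaxPool2d(Layer):
    """2x2 max pooling (both spatial dims must be even)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dy):
        n, c, h, w = self._shape
        dyr = dy[:, :, :, None, :, None] * self._mask
        return dyr.reshape(n, c, h, w)


class Upsample2d(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = self._shape
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred, target):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - np.asarray(target, dtype=pred.dtype)
    return float(np.mean(diff.astype(np.float64) ** 2)), \
        (2.0 / diff.size) * diff


def n_parameters(layer: Layer) -> int:
    return sum(p.value.size for p in layer.params())
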