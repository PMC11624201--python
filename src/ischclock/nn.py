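"""Minimal numpy neural-network layers with manual backpropagation.

Sized for the desk-scale phantoms this package trains on: 2D/3D convolutions
(im2col + one BLAS GEMM), batch normalisation, factor-2 max-pooling and
nearest-neighbour upsampling, linear layers, Adam, and the two losses the
pipeline uses (sigmoid cross-entropy for segmentation, mean absolute error
for age regression). Everything is pure numpy, so training is bitwise
deterministic for a fixed seed.

Tensors are channels-last: ``(N, *spatial, C)``. That layout keeps every
im2col gather and scatter contiguous in the channel dimension, which is what
makes CPU training tractable.
"""

from __future__ import annotations

import itertools

import numpy as np

#: compute dtype; float32 for training speed, switchable to float64 for
#: high-precision gradient verification
DTYPE = np.float32

__all__ = [
    "Conv", "BatchNorm", "ReLU", "MaxPool", "UpsampleNearest", "Linear",
    "GlobalAvgPool", "Sequential", "Adam",
    "bce_with_logits", "mae_loss", "sigmoid",
]


def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv(Layer):
    """N-dimensional 'same' convolution on (N, *S, Cin) -> (N, *S, Cout).

    Weights are stored as (*kernel, Cin, Cout) so the im2col matrix product
    is a single contiguous GEMM in float32.
    """

    def __init__(self, cin, cout, kernel, rng, bias=True):
        if np.isscalar(kernel):
            raise ValueError("kernel must be a tuple (one entry per spatial dim)")
        self.kernel = tuple(kernel)
        self.cin, self.cout = cin, cout
        fan_in = cin * int(np.prod(self.kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(*self.kernel, cin, cout))
        self.W = Param(w.astype(DTYPE))
        self.b = Param(np.zeros(cout, dtype=DTYPE)) if bias else None
        self._offsets = list(itertools.product(*[range(k) for k in self.kernel]))
        self._pads = [(k // 2, k - 1 - k // 2) for k in self.kernel]

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, spatial = x.shape[0], x.shape[1:-1]
        nd = len(spatial)
        xp = np.pad(x, [(0, 0)] + self._pads + [(0, 0)])
        win = np.lib.stride_tricks.sliding_window_view(
            xp, self.kernel, axis=tuple(range(1, 1 + nd)))
        # (N, *S, C, *K) -> (N, *S, *K, C) -> (N*prod(S), prod(K)*C)
        cols = np.moveaxis(win, 1 + nd, -1).reshape(
            n * int(np.prod(spatial)), int(np.prod(self.kernel)) * self.cin)
        wmat = self.W.value.reshape(-1, self.cout)
        y = cols @ wmat
        if self.b is not None:
            y += self.b.value
        self._cols, self._n, self._spatial = cols, n, spatial
        return y.reshape(n, *spatial, self.cout)

    def backward(self, gy):
        n, spatial = self._n, self._spatial
        gym = np.ascontiguousarray(gy, dtype=DTYPE).reshape(-1, self.cout)
        self.W.grad += (self._cols.T @ gym).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += gym.sum(axis=0)
        dcols = (gym @ self.W.value.reshape(-1, self.cout).T).reshape(
            n, *spatial, *self.kernel, self.cin)
        pad_shape = [n] + [s + p0 + p1 for s, (p0, p1)
                           in zip(spatial, self._pads)] + [self.cin]
        dxp = np.zeros(pad_shape, dtype=DTYPE)
        for off in self._offsets:
            dst = (slice(None),) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)) + (slice(None),)
            src = (slice(None),) * (1 + len(spatial)) + off + (slice(None),)
            dxp[dst] += dcols[src]
        crop = (slice(None),) + tuple(
            slice(p0, p0 + s) for (p0, _), s in zip(self._pads, spatial)) \
            + (slice(None),)
        return dxp[crop]


class BatchNorm(Layer):
    """Batch normalisation over the trailing channel axis."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(channels, dtype=DTYPE))
        self.beta = Param(np.zeros(channels, dtype=DTYPE))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(channels, dtype=DTYPE)
        self.run_var = np.ones(channels, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(DTYPE)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.run_mean, self.run_var
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._var, self._axes = var, axes
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, gy):
        axes = self._axes
        self.gamma.grad += (gy * self._xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        gxhat = gy * self.gamma.value
        inv_sd = 1.0 / np.sqrt(self._var + self.eps)
        t1 = gxhat - gxhat.mean(axis=axes)
        t2 = self._xhat * (gxhat * self._xhat).mean(axis=axes)
        return inv_sd * (t1 - t2)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool(Layer):
    """Factor-2 max pooling on all spatial axes (requires even extents)."""

    def forward(self, x, train=True):
        nd = x.ndim - 2
        if any(s % 2 for s in x.shape[1:-1]):
            raise ValueError(f"spatial extents must be even, got {x.shape[1:-1]}")
        shape = [x.shape[0]]
        for s in x.shape[1:-1]:
            shape += [s // 2, 2]
        shape.append(x.shape[-1])
        xr = x.reshape(shape)
        axes = tuple(2 + 2 * i for i in range(nd))
        y = xr.max(axis=axes)
        ye = y.reshape([shape[j] if j not in axes else 1 for j in range(len(shape))])
        mask = (xr == ye)
        self._mask = mask / np.maximum(mask.sum(axis=axes, keepdims=True), 1)
        self._shape_in, self._shape_r, self._axes = x.shape, shape, axes
        return y

    def backward(self, gy):
        shape, axes = self._shape_r, self._axes
        ge = gy.reshape([shape[j] if j not in axes else 1 for j in range(len(shape))])
        return (ge * self._mask).reshape(self._shape_in)


class UpsampleNearest(Layer):
    """Factor-2 nearest-neighbour upsampling on all spatial axes."""

    def forward(self, x, train=True):
        self._shape_in = x.shape
        y = x
        for ax in range(1, x.ndim - 1):
            y = np.repeat(y, 2, axis=ax)
        return y

    def backward(self, gy):
        nd = gy.ndim - 2
        shape = [gy.shape[0]]
        for s in self._shape_in[1:-1]:
            shape += [s, 2]
        shape.append(gy.shape[-1])
        gr = gy.reshape(shape)
        axes = tuple(2 + 2 * i for i in range(nd))
        return gr.sum(axis=axes)


class Linear(Layer):
    def __init__(self, nin, nout, rng):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / nin),
                                  size=(nin, nout)).astype(DTYPE))
        self.b = Param(np.zeros(nout, dtype=DTYPE))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.W.value + self.b.value

    def backward(self, gy):
        gy = np.asarray(gy, dtype=DTYPE)
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


class GlobalAvgPool(Layer):
    """(N, *S, C) -> (N, C) spatial mean."""

    def forward(self, x, train=True):
        self._shape_in = x.shape
        return x.mean(axis=tuple(range(1, x.ndim - 1)))

    def backward(self, gy):
        shape = self._shape_in
        n = int(np.prod(shape[1:-1]))
        g = gy.reshape((shape[0],) + (1,) * (len(shape) - 2) + (shape[-1],))
        return np.broadcast_to(g / n, shape).copy()


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


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
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits, targets, pos_weight=1.0):
    """Mean sigmoid cross-entropy; returns (loss, dloss/dlogits)."""
    z, y = np.asarray(logits, dtype=np.float64), targets
    w = np.where(y > 0.5, pos_weight, 1.0)
    # stable: max(z,0) - z*y + log(1+exp(-|z|)), weighted
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float((w * per).mean())
    grad = (w * (sigmoid(z) - y) / z.size).astype(DTYPE)
    return loss, grad


def mae_loss(pred, target):
    """Mean absolute error; returns (loss, dloss/dpred)."""
    diff = np.asarray(pred, dtype=np.float64) - target
    return float(np.abs(diff).mean()), (np.sign(diff) / diff.size).astype(DTYPE)
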