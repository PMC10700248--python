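"""Minimal 3-D convolutional layer stack (forward + analytic backward).

Dependency-light, CPU-only building blocks used by :mod:`ovaseg.network`.
Arrays are channels-last ``(N, D, H, W, C)``; convolutions use im2col so
the inner loop is a single BLAS matmul.  Every layer caches what its
backward pass needs; ``backward`` consumes the most recent forward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name", "decay")

    def __init__(self, value: np.ndarray, name: str = "", decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name
        # biases / norm parameters are conventionally excluded from weight decay
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """'Same'-padded 3-D convolution with optional per-axis stride."""

    def __init__(self, c_in, c_out, ksize=(3, 3, 3), stride=(1, 1, 1), *,
                 rng: np.random.Generator, dtype=np.float32, name=""):
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.ksize = tuple(int(k) for k in ksize)
        self.stride = tuple(int(s) for s in stride)
        fan_in = self.c_in * int(np.prod(self.ksize))
        w = rng.standard_normal((self.c_in, *self.ksize, self.c_out)) * np.sqrt(2.0 / fan_in)
        self.w = Param(w.astype(dtype), name=f"{name}.w")
        self.b = Param(np.zeros(self.c_out, dtype=dtype), name=f"{name}.b", decay=False)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        kd, kh, kw = self.ksize
        sz, sy, sx = self.stride
        pads = [(k // 2, k // 2) for k in self.ksize]
        xp = np.pad(x, [(0, 0), *pads, (0, 0)])
        win = sliding_window_view(xp, self.ksize, axis=(1, 2, 3))
        win = win[:, ::sz, ::sy, ::sx]  # (N, Do, Ho, Wo, C, kd, kh, kw)
        out_shape = win.shape[:4]
        cols = np.ascontiguousarray(win).reshape(-1, self.c_in * kd * kh * kw)
        wmat = self.w.value.reshape(-1, self.c_out)
        y = cols @ wmat + self.b.value
        self._cache = (cols, x.shape, xp.shape, out_shape)
        return y.reshape(*out_shape, self.c_out)

    def backward(self, dy):
        cols, x_shape, xp_shape, out_shape = self._cache
        kd, kh, kw = self.ksize
        sz, sy, sx = self.stride
        dyf = dy.reshape(-1, self.c_out)
        self.w.grad += (cols.T @ dyf).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.w.value.reshape(-1, self.c_out).T).reshape(
            *out_shape, self.c_in, kd, kh, kw)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        _, do, ho, wo = out_shape
        for iz in range(kd):
            zs = slice(iz, iz + sz * (do - 1) + 1, sz)
            for iy in range(kh):
                ys = slice(iy, iy + sy * (ho - 1) + 1, sy)
                for ix in range(kw):
                    xs = slice(ix, ix + sx * (wo - 1) + 1, sx)
                    dxp[:, zs, ys, xs, :] += dcols[:, :, :, :, :, iz, iy, ix]
        pz, py, px = kd // 2, kh // 2, kw // 2
        _, d, h, w, _ = x_shape
        return dxp[:, pz:pz + d, py:py + h, px:px + w, :]


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel size equal to the stride."""

    def __init__(self, c_in, c_out, stride=(2, 2, 2), *, rng, dtype=np.float32, name=""):
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.stride = tuple(int(s) for s in stride)
        fan_in = self.c_in
        w = rng.standard_normal((*self.stride, self.c_in, self.c_out)) * np.sqrt(2.0 / fan_in)
        self.w = Param(w.astype(dtype), name=f"{name}.w")
        self.b = Param(np.zeros(self.c_out, dtype=dtype), name=f"{name}.b", decay=False)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, d, h, w, _ = x.shape
        sz, sy, sx = self.stride
        y = np.empty((n, d * sz, h * sy, w * sx, self.c_out), dtype=x.dtype)
        xf = x.reshape(-1, self.c_in)
        for iz in range(sz):
            for iy in range(sy):
                for ix in range(sx):
                    block = (xf @ self.w.value[iz, iy, ix] + self.b.value)
                    y[:, iz::sz, iy::sy, ix::sx, :] = block.reshape(n, d, h, w, self.c_out)
        self._cache = (xf, x.shape)
        return y

    def backward(self, dy):
        xf, x_shape = self._cache
        sz, sy, sx = self.stride
        dx = np.zeros(x_shape, dtype=dy.dtype).reshape(-1, self.c_in)
        for iz in range(sz):
            for iy in range(sy):
                for ix in range(sx):
                    dyf = np.ascontiguousarray(dy[:, iz::sz, iy::sy, ix::sx, :]).reshape(-1, self.c_out)
                    self.w.grad[iz, iy, ix] += xf.T @ dyf
                    self.b.grad += dyf.sum(axis=0)
                    dx += dyf @ self.w.value[iz, iy, ix].T
        return dx.reshape(x_shape)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, c, *, eps=1e-5, dtype=np.float32, name=""):
        self.eps = eps
        self.g = Param(np.ones(c, dtype=dtype), name=f"{name}.g", decay=False)
        self.b = Param(np.zeros(c, dtype=dtype), name=f"{name}.b", decay=False)
        self._cache = None

    def params(self):
        return [self.g, self.b]

    def forward(self, x):
        axes = (1, 2, 3)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, x.shape)
        return self.g.value * xhat + self.b.value

    def backward(self, dy):
        xhat, inv, shape = self._cache
        axes = (1, 2, 3)
        m = float(np.prod([shape[a] for a in axes]))
        self.g.grad += (dy * xhat).sum(axis=(0, 1, 2, 3))
        self.b.grad += dy.sum(axis=(0, 1, 2, 3))
        dxhat = dy * self.g.value
        term1 = dxhat.sum(axis=axes, keepdims=True)
        term2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return inv / m * (m * dxhat - term1 - xhat * term2)


class LeakyReLU(Layer):
    def __init__(self, slope=0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class SGDNesterov:
    """SGD with Nesterov momentum and decoupled-from-nothing classic L2 decay.

    Matches the common deep-learning formulation: the L2 term is added to
    the raw gradient before the momentum buffer update.
    """

    def __init__(self, params: list[Param], momentum: float, weight_decay: float):
        self.params = params
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.buffers = [np.zeros_like(p.value) for p in params]

    def step(self, lr: float) -> None:
        m = self.momentum
        for p, buf in zip(self.params, self.buffers):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            buf *= m
            buf += g
            p.value -= np.asarray(lr * (g + m * buf), dtype=p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
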