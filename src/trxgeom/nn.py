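"""Minimal neural-network layers with explicit numpy forward/backward passes.

Everything operates on single samples laid out channel-first, ``(C, H, W)``,
in float64.  Layers cache what their backward pass needs; training here is
batch-size-1 sequential, so one cache per layer suffices.  This is the
computational substrate for the multi-scale residual networks; it favors
clarity and bit-reproducibility over speed.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    __call__ = lambda self, x: self.forward(x)


class Identity(Layer):
    def forward(self, x):
        return x

    def backward(self, dy):
        return dy


class Conv2d(Layer):
    """Same-padding 2D convolution (kernel 1 or 3) with optional dilation.

    He-normal weight init; bias zero.
    """

    def __init__(self, cin: int, cout: int, kernel: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are used here")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, kernel, kernel)))
        self.b = Param(np.zeros(cout))
        self.kernel = kernel
        self.dilation = dilation
        self.cin, self.cout = cin, cout
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        if x.shape[0] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[0]}")
        self._x = x
        if self.kernel == 1:
            y = np.tensordot(self.W.v[:, :, 0, 0], x, axes=([1], [0]))
        else:
            d = self.dilation
            H, Wd = x.shape[1], x.shape[2]
            xp = np.pad(x, ((0, 0), (d, d), (d, d)))
            y = np.zeros((self.cout, H, Wd))
            for a in range(3):
                for b in range(3):
                    patch = xp[:, a * d:a * d + H, b * d:b * d + Wd]
                    y += np.tensordot(self.W.v[:, :, a, b], patch, axes=([1], [0]))
        return y + self.b.v[:, None, None]

    def backward(self, dy):
        x = self._x
        self.b.g += dy.sum(axis=(1, 2))
        if self.kernel == 1:
            self.W.g[:, :, 0, 0] += np.tensordot(dy, x, axes=([1, 2], [1, 2]))
            return np.tensordot(self.W.v[:, :, 0, 0].T, dy, axes=([1], [0]))
        d = self.dilation
        H, Wd = x.shape[1], x.shape[2]
        xp = np.pad(x, ((0, 0), (d, d), (d, d)))
        dxp = np.zeros_like(xp)
        for a in range(3):
            for b in range(3):
                patch = xp[:, a * d:a * d + H, b * d:b * d + Wd]
                self.W.g[:, :, a, b] += np.tensordot(dy, patch, axes=([1, 2], [1, 2]))
                dxp[:, a * d:a * d + H, b * d:b * d + Wd] += np.tensordot(
                    self.W.v[:, :, a, b].T, dy, axes=([1], [0])
                )
        return dxp[:, d:d + H, d:d + Wd]


class InstanceNorm(Layer):
    """Per-channel normalization over the spatial dimensions, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.v[:, None, None] * xhat + self.beta.v[:, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        self.gamma.g += (dy * xhat).sum(axis=(1, 2))
        self.beta.g += dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma.v[:, None, None]
        m1 = dxhat.mean(axis=(1, 2), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._y = None

    def forward(self, x):
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        self._y = y
        return y

    def backward(self, dy):
        y = self._y
        return dy * np.where(y > 0, 1.0, y + self.alpha)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(z: np.ndarray, axis: int = 0) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m *= self.b1
            m += (1.0 - self.b1) * p.g
            s *= self.b2
            s += (1.0 - self.b2) * p.g ** 2
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)
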