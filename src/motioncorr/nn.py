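"""Minimal numpy neural-network layers with explicit forward/backward passes.

Implements exactly the operations the Pix2Pix generator and PatchGAN
discriminator need: strided 4x4 convolution, its transpose, batch
normalization, LeakyReLU/ReLU/tanh, dense layers, a two-class softmax
cross-entropy head and the Adam optimizer.  Data layout is NCHW throughout.

Every layer exposes ``forward(x, train)`` and ``backward(dy)``; parameters are
``Param`` objects accumulating gradients in ``.grad`` until the optimizer
consumes them.  All gradients are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2D",
    "ConvTranspose2D",
    "BatchNorm2D",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Dense",
    "Adam",
    "softmax_cross_entropy",
]


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2D(Layer):
    """Strided 2-D convolution (cross-correlation), weights ~ N(0, 0.02)."""

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = k, stride, pad
        self.W = Param(rng.normal(0.0, 0.02, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.p - self.k) // self.s + 1,
                (w + 2 * self.p - self.k) // self.s + 1)

    def forward(self, x, train=True):
        self._in_shape = x.shape
        xp = _pad_hw(x, self.p)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, ::self.s, ::self.s]
        self._win = win
        y = np.einsum("nchwij,ocij->nohw", win, self.W.value, optimize=True)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        self.W.grad += np.einsum("nohw,nchwij->ocij", dy, self._win, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        n, c, h, w = self._in_shape
        ho, wo = dy.shape[2], dy.shape[3]
        dxp = np.zeros((n, c, h + 2 * self.p, w + 2 * self.p))
        contrib = np.einsum("nohw,ocij->nchwij", dy, self.W.value, optimize=True)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + self.s * ho:self.s,
                    j:j + self.s * wo:self.s] += contrib[:, :, :, :, i, j]
        if self.p:
            return dxp[:, :, self.p:-self.p, self.p:-self.p]
        return dxp


class ConvTranspose2D(Layer):
    """Transposed strided convolution (the adjoint of :class:`Conv2D`).

    With k=4, stride=2, pad=1 an HxW input maps to 2Hx2W, the standard
    Pix2Pix upsampling step.
    """

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = k, stride, pad
        self.W = Param(rng.normal(0.0, 0.02, size=(cin, cout, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        n, cin, h, w = x.shape
        cout = self.W.value.shape[1]
        full_h = (h - 1) * self.s + self.k
        full_w = (w - 1) * self.s + self.k
        full = np.zeros((n, cout, full_h, full_w))
        Wv = self.W.value
        for i in range(self.k):
            for j in range(self.k):
                full[:, :, i:i + self.s * h:self.s,
                     j:j + self.s * w:self.s] += np.einsum(
                         "nihw,io->nohw", x, Wv[:, :, i, j], optimize=True)
        if self.p:
            full = full[:, :, self.p:-self.p, self.p:-self.p]
        return full + self.b.value[None, :, None, None]

    def backward(self, dy):
        x = self._x
        n, cin, h, w = x.shape
        dyp = _pad_hw(dy, self.p)
        dx = np.zeros_like(x)
        Wv = self.W.value
        for i in range(self.k):
            for j in range(self.k):
                sl = dyp[:, :, i:i + self.s * h:self.s, j:j + self.s * w:self.s]
                dx += np.einsum("nohw,io->nihw", sl, Wv[:, :, i, j], optimize=True)
                self.W.grad[:, :, i, j] += np.einsum(
                    "nihw,nohw->io", x, sl, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, train)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, dy):
        xhat, ivar, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dy * g * ivar[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - sum_dxhat / m - xhat * sum_dxhat_xhat / m)
        return dx * ivar[None, :, None, None]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, 0.02, size=(nin, nout)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def softmax_cross_entropy(logits: np.ndarray, target_index: int):
    """Mean two-class softmax cross-entropy over rows of ``logits``.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss.  ``target_index`` is the true class shared by all rows.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.maximum(p[:, target_index], 1e-12)).mean()
    dlogits = p.copy()
    dlogits[:, target_index] -= 1.0
    return loss, dlogits / n


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
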