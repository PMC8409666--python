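"""Minimal NumPy neural-network core: 2D layers with manual backprop + Adam.

Only what the encoder-decoder segmentation network needs: same-padded 2D
convolution, batch normalization, ReLU, 2x2 max pooling, 2x2 nearest
upsampling, channel concatenation and a sigmoid head.  Arrays are NCHW,
float32; gradients are accumulated per parameter between ``zero_grad``
calls.  Everything is deterministic given the initialization seed and a
fixed BLAS thread count.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("val", "grad")

    def __init__(self, val: np.ndarray):
        self.val = np.asarray(val, dtype=np.float32)
        self.grad = np.zeros_like(self.val)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded 2D convolution with odd square kernels (1x1 or 3x3)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = kernel * kernel * c_in
        limit = np.sqrt(6.0 / fan_in)  # He-uniform
        self.W = Param(rng.uniform(-limit, limit, size=(kernel, kernel, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._xpad: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.k // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if train:
            self._xpad = xpad
        n, c, h, w = x.shape
        y = np.empty((n, self.c_out, h, w), dtype=np.float32)
        y[:] = self.b.val[None, :, None, None]
        for ki in range(self.k):
            for kj in range(self.k):
                y += np.einsum("nchw,cf->nfhw", xpad[:, :, ki:ki + h, kj:kj + w],
                               self.W.val[ki, kj], optimize=True)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xpad = self._xpad
        n, _, h, w = dy.shape
        p = self.k // 2
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxpad = np.zeros_like(xpad)
        for ki in range(self.k):
            for kj in range(self.k):
                xs = xpad[:, :, ki:ki + h, kj:kj + w]
                self.W.grad[ki, kj] += np.einsum("nchw,nfhw->cf", xs, dy, optimize=True)
                dxpad[:, :, ki:ki + h, kj:kj + w] += np.einsum(
                    "nfhw,cf->nchw", dy, self.W.val[ki, kj], optimize=True)
        return dxpad if p == 0 else dxpad[:, :, p:-p, p:-p]


class BatchNorm2d(Layer):
    """Per-channel batch normalization; running stats used at eval time."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._xhat, self._inv = xhat, inv
            self._m = x.shape[0] * x.shape[2] * x.shape[3]
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return (self.gamma.val[None, :, None, None] * xhat
                + self.beta.val[None, :, None, None]).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.val[None, :, None, None]
        # standard batchnorm backward over the (N,H,W) reduction axes
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] * (term1 - term2 - term3)).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._pos = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h},{w}) not divisible by 2")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xw = xr.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._arg = xw.argmax(axis=-1)
            self._shape = (n, c, h, w)
        return xw.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dwin, self._arg[..., None], dy[..., None], axis=-1)
        return (dwin.reshape(n, c, h // 2, w // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))


class Upsample2(Layer):
    """Non-learned 2x2 nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer; ``beta1`` is the momentum term (0.5 in this pipeline)."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
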