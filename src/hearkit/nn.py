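"""Minimal CNN building blocks on numpy.

Implements exactly the layers the scene classifier needs — 3x3 same-padding
convolution, batch normalisation, ReLU, 2x2 max pooling, dense layers,
inverted dropout, softmax cross-entropy — with explicit backward passes and
an Adam optimiser.  Convolutions are expressed as im2col + GEMM in both
directions so everything runs through BLAS; all gradients are verified
against numerical differentiation in the test suite.

Tensors are NCHW.  Default dtype is float32 for speed; float64 is available
for gradient checking.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _im2col3x3(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*9) patches with zero padding 1 (same size)."""
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * 9)


class Layer:
    trainable = False

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, train):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero ('same') padding."""

    trainable = True

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, dtype=np.float32):
        fan_in = in_channels * 9
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.W = (rng.standard_normal((out_channels, fan_in)) * scale).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.in_channels = in_channels
        self.out_channels = out_channels

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        B, C, H, W = x.shape
        self._shape = x.shape
        self._cols = _im2col3x3(x)  # (B, H*W, C*9)
        out = self._cols @ self.W.T + self.b  # (B, H*W, F)
        return out.transpose(0, 2, 1).reshape(B, self.out_channels, H, W)

    def backward(self, dy):
        B, F, H, W = dy.shape
        dym = dy.reshape(B, F, H * W).transpose(0, 2, 1)  # (B, H*W, F)
        self.dW = np.einsum("bpf,bpc->fc", dym, self._cols, optimize=True)
        self.db = dym.sum(axis=(0, 1))
        # dx = 'full' correlation of dy with the spatially flipped kernels
        Wk = self.W.reshape(F, self.in_channels, 3, 3)
        Wrot = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_channels, F * 9)
        dcols = _im2col3x3(dy)  # (B, H*W, F*9)
        dx = dcols @ Wrot.T  # (B, H*W, C)
        return dx.transpose(0, 2, 1).reshape(self._shape)


class BatchNorm2D(Layer):
    """Per-channel batch normalisation over (batch, height, width)."""

    trainable = True

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        N = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma = (dy * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * self._istd[None, :, None, None]
        dy_sum = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        dyx_sum = (dy * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g * (dy - dy_sum / N - self._xhat * dyx_sum / N)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, train):
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        self._in_shape = x.shape
        xr = x[:, :, : H2 * 2, : W2 * 2].reshape(B, C, H2, 2, W2, 2)
        patches = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
        self._idx = patches.argmax(axis=-1)
        return patches.max(axis=-1)

    def backward(self, dy):
        B, C, H2, W2 = dy.shape
        onehot = self._idx[..., None] == np.arange(4)
        dpatch = dy[..., None] * onehot  # (B, C, H2, W2, 4)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dxr = dpatch.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx[:, :, : H2 * 2, : W2 * 2] = dxr.reshape(B, C, H2 * 2, W2 * 2)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / in_features)
        self.W = (rng.standard_normal((in_features, out_features)) * scale).astype(dtype)
        self.b = np.zeros(out_features, dtype=dtype)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params()))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999) updating parameters in place."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
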