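"""Minimal deterministic feed-forward network engine.

Implements exactly the layer vocabulary the dual-branch classifier needs —
3x3 same-padding convolution, ReLU, 2x2 max pooling, inverted dropout,
flatten, dense — with manual backpropagation, softmax cross-entropy loss and
an Adam optimizer.  Everything runs on numpy arrays in float64; a single
`numpy.random.Generator` drives initialization, shuffling and dropout so a
fixed seed reproduces training bit-for-bit on one thread.

Array layout: convolutional tensors are (N, C, H, W); dense activations are
(N, D).  Parameters and activations are float32 (single precision is ample
for these small networks and roughly halves the arithmetic cost).
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base layer; stateless layers override forward/backward only."""

    def forward(self, x: np.ndarray, *, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)  # He initialization
        self.W = rng.normal(0.0, scale, size=(in_features, out_features)).astype(DTYPE)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, *, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Conv2D(Layer):
    """3x3 convolution, stride 1, zero same-padding, via im2col."""

    KERNEL = 3

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        k = self.KERNEL
        fan_in = in_channels * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.KERNEL
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)

    def forward(self, x, *, train, rng):
        n, c, h, w = x.shape
        self._shape = x.shape
        cols = self._im2col(x)
        self._cols = cols
        out = cols @ self.W + self.b
        return out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w = self._shape
        k = self.KERNEL
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        gcols = (g @ self.W.T).reshape(n, h, w, c, k, k)
        gx = np.zeros((n, c, h + 2, w + 2), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + h, j : j + w] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gx[:, :, 1 : 1 + h, 1 : 1 + w]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, *, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are cropped."""

    def forward(self, x, *, train, rng):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : 2 * h2, : 2 * w2]
        self._in_shape = (n, c, h, w)
        xr = x.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        h2, w2 = grad.shape[2], grad.shape[3]
        onehot = np.eye(4, dtype=DTYPE)[self._argmax]  # (n, c, h2, w2, 4)
        g = (grad[..., None] * onehot).reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros((n, c, h, w), dtype=DTYPE)
        gx[:, :, : 2 * h2, : 2 * w2] = g.reshape(n, c, 2 * h2, 2 * w2)
        return gx


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at prediction."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, *, train, rng):
        if not train or self.rate == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(DTYPE)
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, *, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, *, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = (logits - logits.max(axis=1, keepdims=True)).astype(np.float64)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    return float(-np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean())


def softmax_ce_grad(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = len(labels)
    grad = probs.astype(DTYPE)
    grad[np.arange(n), labels] -= 1.0
    return grad / DTYPE(n)


class Adam:
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            if self.weight_decay > 0.0 and p.ndim > 1:  # decay weights, not biases
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def snapshot_params(params: list[np.ndarray]) -> list[np.ndarray]:
    return [p.copy() for p in params]


def restore_params(params: list[np.ndarray], saved: list[np.ndarray]) -> None:
    for p, s in zip(params, saved):
        p[...] = s


def clone_layers(seq: Sequential) -> Sequential:
    return copy.deepcopy(seq)
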