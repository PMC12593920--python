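"""Minimal convolutional-network layers with explicit backpropagation.

A small, self-contained layer stack (3x3 same-padding convolutions, 2x2
max pooling, fully connected head) trained with stochastic gradient
descent with momentum and weight decay under a cross-entropy loss.  Every
layer exposes ``forward``/``backward``; the explicit backward pass is what
lets Grad-CAM pull gradients of a class logit with respect to an
intermediate feature map.

Data layout is NHWC throughout.  A 3x3 convolution assembles its column
matrix by writing the nine shifted views of the padded input into one
contiguous buffer and then runs a single GEMM, which keeps the data
movement sequential and the BLAS call well-shaped.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless unless it owns parameters."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """kxk same-padding convolution over NHWC input."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.W = (rng.standard_normal((k, k, in_ch, out_ch))
                  * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        oh, ow = h + 2 * p - k + 1, w + 2 * p - k + 1
        cols = np.empty((n * oh * ow, k * k * c), dtype=x.dtype)
        cols6 = cols.reshape(n, oh, ow, k, k * c)
        xpf = xp.reshape(n, h + 2 * p, (w + 2 * p) * c)
        it = xp.itemsize
        for di in range(k):
            sub = xpf[:, di:di + oh, :]
            src = np.lib.stride_tricks.as_strided(
                sub, shape=(n, oh, ow, k * c),
                strides=(sub.strides[0], sub.strides[1], c * it, it))
            cols6[:, :, :, di, :] = src
        out = cols @ self.W.reshape(k * k * c, self.out_ch) + self.b
        if train:
            self._cache = (cols, (n, h, w, c, oh, ow))
        return out.reshape(n, oh, ow, self.out_ch)

    def backward(self, grad, need_input_grad: bool = True):
        cols, (n, h, w, c, oh, ow) = self._cache
        p, k = self.pad, self.k
        g = grad.reshape(-1, self.out_ch)
        self.db[...] = g.sum(axis=0)
        self.dW[...] = (cols.T @ g).reshape(self.W.shape)
        if not need_input_grad:
            return None
        dcols = g @ self.W.reshape(k * k * c, self.out_ch).T
        dcols6 = dcols.reshape(n, oh, ow, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=grad.dtype)
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + oh, dj:dj + ow, :] += dcols6[:, :, :, di, dj, :]
        return dxp[:, p:p + h, p:p + w, :]

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling (input H, W assumed even)."""

    def forward(self, x, train=False):
        a, b = x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :]
        c, d = x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]
        m1 = np.maximum(a, b)
        m2 = np.maximum(c, d)
        out = np.maximum(m1, m2)
        if train:
            # first-occurrence argmax in (a, b, c, d) order, ties to earliest
            sel = m2 > m1
            idx = np.where(sel,
                           2 + (d > c).astype(np.int8),
                           (b > a).astype(np.int8)).astype(np.int8)
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._shape
        dx = np.zeros((n, h, w, c), dtype=grad.dtype)
        slices = ((0, 0), (0, 1), (1, 0), (1, 1))
        for q, (i, j) in enumerate(slices):
            dx[:, i::2, j::2, :] = np.where(self._idx == q, grad, 0)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if train:
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

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def forward_from(self, x, start: int, train=False):
        for layer in self.layers[start:]:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad, stop: int = 0):
        """Backpropagate down to (and excluding) layer index ``stop``;
        returns the gradient flowing into layer ``stop``.  When ``stop`` is
        0 the gradient w.r.t. the network input is not materialized (the
        first convolution only needs its weight gradients)."""
        for i in range(len(self.layers) - 1, stop - 1, -1):
            layer = self.layers[i]
            if i == 0 and stop == 0 and isinstance(layer, Conv2d):
                return layer.backward(grad, need_input_grad=False)
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class SGD:
    """Classic SGD with momentum and L2 weight decay folded into the
    gradient: v <- mu*v - lr*(g + wd*w);  w <- w + v."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * (g + self.weight_decay * p)
            p += v
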