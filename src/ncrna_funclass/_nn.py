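"""Minimal feed-forward neural-network primitives in NumPy.

Implements exactly the layer set the hybrid classifier needs — strided 1-D
convolution over (position x channel) input via im2col, average pooling,
dense layers, ReLU, inverted dropout — with explicit backpropagation and an
Adam optimizer.  All randomness (initialization, dropout masks) flows from a
caller-supplied ``numpy.random.Generator``, making training bit-reproducible
in single-threaded runs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "AvgPool1D",
    "ReLU",
    "Dropout",
    "Flatten",
    "Adam",
    "softmax",
    "softmax_cce",
]

_DTYPE = np.float32


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.b = np.zeros(d_out, dtype=_DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1D(Layer):
    """Strided 1-D convolution over input shaped (N, length, channels).

    The first conv of the network consumes the one-hot matrix directly, so a
    kernel spanning all input channels makes it equivalent to a 2-D
    convolution whose second dimension covers the 4 base channels.
    """

    def __init__(self, in_ch: int, filters: int, kernel: int, stride: int, rng):
        self.kernel = kernel
        self.stride = stride
        self.in_ch = in_ch
        self.filters = filters
        fan_in = kernel * in_ch
        self.W = _glorot(rng, fan_in, filters, (fan_in, filters))
        self.b = np.zeros(filters, dtype=_DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_length(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def forward(self, x, training):
        n, length, c = x.shape
        out_l = self.out_length(length)
        starts = np.arange(out_l) * self.stride
        idx = starts[:, None] + np.arange(self.kernel)[None, :]
        cols = x[:, idx, :].reshape(n, out_l, self.kernel * c)  # im2col
        self._cols = cols
        self._in_shape = x.shape
        return cols @ self.W + self.b

    def backward(self, grad):
        n, out_l, _ = grad.shape
        cols2 = self._cols.reshape(-1, self.kernel * self.in_ch)
        g2 = grad.reshape(-1, self.filters)
        self.dW[...] = cols2.T @ g2
        self.db[...] = g2.sum(axis=0)
        dcols = (grad @ self.W.T).reshape(n, out_l, self.kernel, self.in_ch)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        starts = np.arange(out_l) * self.stride
        # for fixed kernel offset j the target positions are all distinct
        for j in range(self.kernel):
            dx[:, starts + j, :] += dcols[:, :, j, :]
        return dx


class AvgPool1D(Layer):
    """Non-overlapping average pooling along the position axis (floor mode)."""

    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, training):
        n, length, c = x.shape
        out_l = length // self.pool
        self._in_shape = x.shape
        self._out_l = out_l
        trimmed = x[:, : out_l * self.pool, :].reshape(n, out_l, self.pool, c)
        return trimmed.mean(axis=2)

    def backward(self, grad):
        n, out_l, c = grad.shape
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        expanded = np.repeat(grad / self.pool, self.pool, axis=1)
        dx[:, : out_l * self.pool, :] = expanded
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cce(logits: np.ndarray, targets: np.ndarray):
    """Softmax + categorical cross-entropy, fused for a stable gradient.

    Returns (mean loss, probabilities, gradient w.r.t. logits).  With one-hot
    targets the per-sample loss is -sum_i t_i log p_i.
    """
    probs = softmax(logits)
    eps = np.finfo(np.float64).tiny
    loss = -np.mean(np.sum(targets * np.log(np.maximum(probs, eps)), axis=1))
    dlogits = (probs - targets) / logits.shape[0]
    return float(loss), probs, dlogits.astype(logits.dtype)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
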