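"""Minimal dense-network building blocks with manual backprop and Adam.

Everything operates on float64 arrays of shape (n_samples, n_features).
This is deliberately tiny: the translator's generators and discriminators
are per-pixel intensity networks, so dense layers on flattened pixels are
all that is needed, and a handful of NumPy ops keeps training bit-exactly
reproducible on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam"]


class Dense:
    """Fully-connected layer with optional ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool = True, scale: float | None = None):
        scale = scale if scale is not None else np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.relu = relu
        self._x = None
        self._pre = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        pre = x @ self.w + self.b
        if self.relu:
            self._pre = pre
            return np.maximum(pre, 0.0)
        return pre

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.relu:
            grad = grad * (self._pre > 0)
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.gw, self.gb]


class MLP:
    """A stack of Dense layers; the last layer is linear."""

    def __init__(self, sizes: list[int], rng: np.random.Generator, out_scale: float = 0.05):
        self.layers = []
        for i in range(len(sizes) - 1):
            last = i == len(sizes) - 2
            self.layers.append(
                Dense(sizes[i], sizes[i + 1], rng, relu=not last, scale=out_scale if last else None)
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr: float = 2e-4, beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
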