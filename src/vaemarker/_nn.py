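"""Minimal dense neural-net stack: layers, Adam, and manual backprop.

Just enough machinery for an encoder/decoder/classifier built from fully
connected layers with LeakyReLU activations.  Everything is float64 numpy and
fully deterministic given a seeded Generator, which is what makes the training
and attribution contracts reproducible.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Dense:
    """Affine layer with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    def parameters(self) -> list[Param]:
        return [self.W, self.b]


class LeakyReLU:
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.slope * g)

    def parameters(self) -> list[Param]:
        return []


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                # decoupled decay; spreads weight across redundant features
                p.value -= self.lr * self.weight_decay * p.value


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def bce_with_logits(x: np.ndarray, logits: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-over-batch, sum-over-features binary cross-entropy.

    Returns (loss, grad wrt logits).  Targets x must lie in [0, 1].
    """
    n = x.shape[0]
    # softplus(l) - x*l, computed stably
    loss = float(np.sum(np.logaddexp(0.0, logits) - x * logits) / n)
    grad = (sigmoid(logits) - x) / n
    return loss, grad


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy for integer class labels; returns grad too."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logsum - z[np.arange(n), y]))
    grad = softmax(logits)
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n
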