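"""Layers, parameter containers, and the Adam optimizer used by all models."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    """Affine map x @ W + b with Glorot-uniform initialization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = parameter(glorot(rng, in_dim, out_dim))
        self.b = parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Stack of Linear layers with leaky-ReLU between hidden layers."""

    def __init__(self, dims, rng, slope: float = 0.2, out_activation=None):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.slope = slope
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = ad.leaky_relu(layer(x), self.slope)
        x = self.layers[-1](x)
        if self.out_activation is not None:
            x = self.out_activation(x)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Embedding:
    """Learned lookup table mapping integer codes to dense rows."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.table = parameter(rng.normal(scale=0.1, size=(vocab_size, dim)))

    def __call__(self, idx) -> Tensor:
        return ad.take_rows(self.table, np.asarray(idx, dtype=np.intp))

    def parameters(self):
        return [self.table]


class Adam:
    """Adam with bias correction; operates in place on parameter arrays."""

    def __init__(self, params, lr=1e-4, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def parameters_checksum(params) -> float:
    """Order-sensitive checksum over parameter arrays (reproducibility tests)."""
    total = 0.0
    for i, p in enumerate(params):
        total += float(np.sum(p.data * np.cos(np.arange(p.data.size).reshape(p.data.shape) + i)))
    return total
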