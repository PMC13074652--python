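"""Minimal feed-forward neural-network toolkit (numpy, manual backprop).

Provides exactly the pieces the augmentation VAE and the FFNN regressor
need: dense layers, batch normalization, ReLU / LeakyReLU, inverted
dropout, and Adam.  Everything is deterministic given the
``numpy.random.Generator`` passed in; parameters are float64.

This is intentionally a small, auditable implementation — the networks
in this package have a few thousand parameters and train on tables of a
few hundred to a few thousand rows, where a hand-rolled numpy loop is
fast and dependency-free.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "BatchNorm", "ReLU", "LeakyReLU", "Dropout", "Sequential", "Adam"]


class Layer:
    """Interface: forward(x, train) -> out; backward(grad) -> grad_in."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine layer, He-normal initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class BatchNorm(Layer):
    """Batch normalization with running statistics for inference."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        xhat = self._xhat
        self.grads[0][...] = (grad * xhat).sum(axis=0)
        self.grads[1][...] = grad.sum(axis=0)
        gx = grad * self.gamma
        # standard batchnorm backward through batch mean/var
        return (gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)) / self._std


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        for lay in layers:
            self.params.extend(lay.params)
            self.grads.extend(lay.grads)

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, grad):
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        return grad


class Adam:
    """Adam with the standard bias correction; updates params in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled near-equal batches (avoids stray size-1 batches)."""
    idx = rng.permutation(n)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    return np.array_split(idx, n_batches)
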