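"""Minimal numpy neural-network layer toolkit with manual backpropagation.

Fully-connected layers and the handful of activations needed by the
generator / critic / encoder triple, plus an Adam optimizer.  Weights and
activations are float32 (training is bandwidth-bound at these layer sizes)
and all randomness flows through an explicit ``numpy.random.Generator``,
so training is bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "ReLU", "LeakyReLU", "Sigmoid", "Sequential", "Adam"]

DTYPE = np.float32


class Dense:
    """Affine layer ``y = x @ W + b`` with cached input for backprop."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 w_scale: float | None = None):
        if w_scale is None:
            # He-style fan-in scaling works for both ReLU and leaky units.
            w_scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, w_scale, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray, need_input_grad: bool = True):
        self.dW += self._x.T @ grad_out
        self.db += grad_out.sum(axis=0)
        if not need_input_grad:
            return None
        return grad_out @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    params = ()
    grads = ()

    def zero_grad(self):
        pass


class LeakyReLU:
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        self._slope = np.where(x > 0, 1.0, self.alpha)
        return x * self._slope

    def backward(self, g):
        return g * self._slope

    params = ()
    grads = ()

    def zero_grad(self):
        pass


class Sigmoid:
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)

    params = ()
    grads = ()

    def zero_grad(self):
        pass


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backpropagate, accumulating parameter grads; returns input grad."""
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    # -- flat (de)serialization -------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    """Adam over a fixed parameter list; state arrays mirror the params."""

    def __init__(self, params, grads, lr: float, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.gradrefs = list(grads)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, self.gradrefs, self.m, self.v):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
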