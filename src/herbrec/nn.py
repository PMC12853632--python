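"""Minimal feed-forward network core: dense layers, ReLU, Adam.

All models in this package are small multilayer perceptrons trained on a
single CPU, so the forward/backward passes are written directly in numpy.
Every source of randomness goes through a caller-supplied
``numpy.random.Generator``, which makes whole training runs pure functions
of (data, config, seed).
"""

from __future__ import annotations

import numpy as np

__all__ = ["relu", "relu_grad", "sigmoid", "Dense", "ReLU", "Sequential", "Adam", "he_uniform"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(pre: np.ndarray) -> np.ndarray:
    # subgradient 0 at exactly 0
    return (pre > 0).astype(pre.dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def he_uniform(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Fan-in scaled uniform initialization suited to ReLU stacks."""
    limit = np.sqrt(6.0 / n_in)
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Dense:
    """Affine layer ``x @ W + b`` with cached input for backprop."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = he_uniform(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU:
    def __init__(self):
        self._pre: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pre = x
        return relu(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * relu_grad(self._pre)

    def params(self):
        return []

    def grads(self):
        return []


class Sequential:
    """A stack of layers with explicit forward/backward passes.

    ``backward`` accumulates parameter gradients (call :meth:`zero_grad`
    between optimizer steps); this lets adversarial branches send several
    scaled gradient signals through a shared trunk in one step.
    """

    def __init__(self, layers):
        self.layers = list(layers)

    @classmethod
    def mlp(cls, rng: np.random.Generator, widths: list[int], final_relu: bool = True) -> "Sequential":
        """Fully connected ReLU stack through the given layer widths.

        ``widths = [in, h1, ..., out]`` produces ``len(widths) - 1`` dense
        layers with ReLU after each, the last one included iff ``final_relu``.
        """
        layers: list = []
        n_dense = len(widths) - 1
        for i in range(n_dense):
            layers.append(Dense(rng, widths[i], widths[i + 1]))
            if i < n_dense - 1 or final_relu:
                layers.append(ReLU())
        return cls(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def sq_norm(self) -> float:
        """Sum of squared entries over every parameter array."""
        return float(sum(np.sum(p * p) for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p[...] = s


class Adam:
    """Adam with optional decoupled-style L2 (gradient gets ``2*wd*param``)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], weight_decay: float = 0.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            if weight_decay:
                g = g + 2.0 * weight_decay * p
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
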