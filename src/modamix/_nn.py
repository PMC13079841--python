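"""Minimal feed-forward neural-network core.

Implements exactly the building blocks the model needs — affine layers,
batch normalization, LeakyReLU, softmax cross-entropy gradients and the Adam
optimizer — with hand-derived reverse-mode gradients on numpy arrays.
Forward passes cache activations; ``backward`` consumes the upstream
gradient, accumulates parameter gradients and returns the input gradient.

Training mode uses per-batch statistics in batch-norm layers (and updates the
running estimates); inference mode uses the running estimates, which makes
inference deterministic for fixed parameters.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    """Affine map with Kaiming fan-in initialization for LeakyReLU layers."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain_slope: float = 0.01):
        std = np.sqrt(2.0 / ((1.0 + gain_slope**2) * n_in))
        self.W = Parameter(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class BatchNorm(Layer):
    """1-D batch normalization with learnable scale/shift.

    Running statistics are exponential moving averages (momentum 0.1) used in
    inference mode only.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = grad.shape[0]
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        # standard batch-norm input gradient
        return inv_std / n * (n * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = np.asarray(grad, dtype=DTYPE)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


def mlp(
    n_in: int,
    hidden: list[int],
    n_out: int | None,
    rng: np.random.Generator,
    slope: float = 0.01,
) -> Sequential:
    """Build Linear+BatchNorm+LeakyReLU hidden blocks, plus an optional
    final linear output layer (``n_out=None`` makes the last hidden block the
    output, as in the feature extractors)."""
    layers: list[Layer] = []
    d = n_in
    for h in hidden:
        layers.append(Linear(d, h, rng, gain_slope=slope))
        layers.append(BatchNorm(h))
        layers.append(LeakyReLU(slope))
        d = h
    if n_out is not None:
        layers.append(Linear(d, n_out, rng, gain_slope=slope))
    return Sequential(layers)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam with default moments (beta1=0.9, beta2=0.999, eps=1e-8).

    Accepts (parameter-list, learning-rate) groups so each network component
    can keep its own learning rate inside one optimizer.
    """

    def __init__(self, groups: list[tuple[list[Parameter], float]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.groups = [(list(params), lr) for params, lr in groups]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {
            id(p): (np.zeros_like(p.value), np.zeros_like(p.value))
            for params, _ in self.groups
            for p in params
        }

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for params, lr in self.groups:
            for p in params:
                m, v = self.state[id(p)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad**2
                p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for params, _ in self.groups:
            for p in params:
                p.grad[...] = 0.0
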