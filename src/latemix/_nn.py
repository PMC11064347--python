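"""Minimal dense-network primitives: layers, LeakyReLU, dropout, Adam.

Explicit forward/backward passes on NumPy arrays; no autograd. The networks
built from these pieces are small (a few hundred to a few hundred thousand
weights) and train comfortably on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["leaky_relu", "leaky_relu_grad", "Dense", "Dropout", "Adam"]


def leaky_relu(u: np.ndarray, slope: float) -> np.ndarray:
    """Identity for positive inputs, ``slope * u`` otherwise."""
    return np.where(u > 0, u, slope * u)


def leaky_relu_grad(u: np.ndarray, slope: float) -> np.ndarray:
    return np.where(u > 0, 1.0, slope)


class Dense:
    """Fully connected layer with optional LeakyReLU activation.

    Parameters are He-initialised from the layer fan-in. ``activation`` is
    either ``"leaky"`` or ``"linear"``; the final decoder / head layers of the
    autoencoder are linear.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "leaky", slope: float = 0.1):
        if activation not in ("leaky", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.slope = slope
        self.trainable = True
        self._x = None
        self._z = None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        z = x @ self.W + self.b
        if cache:
            self._x, self._z = x, z
        if self.activation == "leaky":
            return leaky_relu(z, self.slope)
        return z

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Propagate the loss gradient; accumulates gW/gb from the cached pass."""
        if self.activation == "leaky":
            grad_out = grad_out * leaky_relu_grad(self._z, self.slope)
        self.gW = self._x.T @ grad_out
        self.gb = grad_out.sum(axis=0)
        return grad_out @ self.W.T


class Dropout:
    """Inverted dropout: active mask is rescaled by 1/(1-rate) in training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, rng: np.random.Generator | None,
                training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Adam:
    """Adam optimiser over the trainable parameters of a list of Dense layers."""

    def __init__(self, layers: list[Dense], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]
        self._v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in layers]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for i, layer in enumerate(self.layers):
            if not layer.trainable:
                continue
            for j, (param, grad) in enumerate(((layer.W, layer.gW), (layer.b, layer.gb))):
                m = self._m[i][j]
                v = self._v[i][j]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                param -= lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
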