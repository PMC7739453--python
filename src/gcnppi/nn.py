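"""Minimal dense neural-network layers with explicit backpropagation.

Implements exactly the pieces the pair classifier needs — affine layers,
batch normalization, inverted dropout, the rectifier, and a softmax
cross-entropy head — as NumPy float64 operations with hand-written
gradients.  Gradients are validated against finite differences in the
test suite.  Evaluation mode is fully deterministic: dropout is disabled
and batch normalization uses running statistics.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: trainable layers expose named parameters and gradients."""

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0


class Linear(Layer):
    """Affine map ``x @ W + b`` with fan-in-scaled uniform initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        bound = 1.0 / np.sqrt(d_in)
        self.W = rng.uniform(-bound, bound, size=(d_in, d_out)).astype(dtype)
        self.b = rng.uniform(-bound, bound, size=d_out).astype(dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ dout
        self.gb += dout.sum(axis=0)
        return dout @ self.W.T

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def gradients(self):
        return {"W": self.gW, "b": self.gb}


class BatchNorm1d(Layer):
    """Batch normalization over the batch axis.

    Training mode normalizes with batch statistics and updates running
    estimates; evaluation mode uses the running estimates, making the
    forward pass deterministic.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = np.ones(dim, dtype=dtype)
        self.beta = np.zeros(dim, dtype=dtype)
        self.ggamma = np.zeros(dim, dtype=dtype)
        self.gbeta = np.zeros(dim, dtype=dtype)
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * inv_std
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
            self._cache = (xhat, inv_std)
            return self.gamma * xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0]
        self.ggamma += (dout * xhat).sum(axis=0)
        self.gbeta += dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p)
                      .astype(x.dtype) / (1.0 - self.p))
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.parameters().items():
                out[f"{i}.{name}"] = p
        return out

    def gradients(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for name, g in layer.gradients().items():
                out[f"{i}.{name}"] = g
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of a 2-way softmax against integer labels.

    Returns the scalar loss and the gradient w.r.t. the logits.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


def sgd_step(layers: list[Layer], lr: float) -> None:
    """In-place vanilla SGD update over all trainable parameters."""
    for layer in layers:
        params, grads = layer.parameters(), layer.gradients()
        for name in params:
            params[name] -= lr * grads[name]
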