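"""Minimal feed-forward neural-network primitives in numpy.

Dense layers, batch / layer normalization, SELU and AlphaDropout, the Adam
optimizer and global-norm gradient clipping, with explicit reverse-mode
gradients. Only what the compressor-generator model needs; batched 2-D
inputs throughout.

Numerical conventions: LeCun-normal weight initialization (the standard for
self-normalizing SELU networks), biased batch variance both for
normalization and for the running statistics, batch-norm momentum 0.1,
eps 1e-5.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "BatchNorm1d",
    "LayerNorm",
    "SELU",
    "AlphaDropout",
    "Sequential",
    "Adam",
    "clip_grad_norm",
]

SELU_ALPHA = 1.6732632423543772848170429916717
SELU_SCALE = 1.0507009873554804934193349852946


class Layer:
    """Base class: parameters and their gradients are parallel dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def state(self) -> dict[str, np.ndarray]:
        """All arrays needed to restore the layer (params + buffers)."""
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


class Dense(Layer):
    """Affine layer ``y = x @ W + b`` with LeCun-normal init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        if n_in <= 0 or n_out <= 0:
            raise ValueError("layer widths must be positive")
        self.n_in, self.n_out = n_in, n_out
        self.params = {
            "W": rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class BatchNorm1d(Layer):
    """Batch normalization over the batch axis with running statistics.

    Training uses batch mean/variance (biased) and updates the running
    buffers; eval normalizes with the accumulated statistics, so eval-mode
    output is deterministic and batch-independent.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._istd
            return self.params["gamma"] * self._xhat + self.params["beta"]
        return (
            self.params["gamma"] * (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
            + self.params["beta"]
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        xhat, istd = self._xhat, self._istd
        self.grads["gamma"] = (dout * xhat).sum(axis=0)
        self.grads["beta"] = dout.sum(axis=0)
        dxhat = dout * self.params["gamma"]
        return (istd / n) * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))

    def state(self) -> dict[str, np.ndarray]:
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        super().load_state(state)
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


class LayerNorm(Layer):
    """Per-sample normalization over features (off by default in the model)."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout.shape[1]
        xhat, istd = self._xhat, self._istd
        self.grads["gamma"] = (dout * xhat).sum(axis=0)
        self.grads["beta"] = dout.sum(axis=0)
        dxhat = dout * self.params["gamma"]
        return (istd / d) * (
            d * dxhat
            - dxhat.sum(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
        )


class SELU(Layer):
    """Scaled exponential linear unit (self-normalizing activation)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        neg = x <= 0
        out = np.where(neg, SELU_SCALE * SELU_ALPHA * np.expm1(np.minimum(x, 0.0)), SELU_SCALE * x)
        if train:
            self._deriv = np.where(neg, SELU_SCALE * SELU_ALPHA * np.exp(np.minimum(x, 0.0)), SELU_SCALE)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._deriv


class AlphaDropout(Layer):
    """Dropout variant that preserves the self-normalizing property of SELU.

    Dropped units are set to the SELU saturation value -scale*alpha, then the
    output is affinely rescaled so mean and variance are preserved. Identity
    when rate is 0 or in eval mode.
    """

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        ap = -SELU_SCALE * SELU_ALPHA
        q = 1.0 - rate
        self._a = (q + ap**2 * q * rate) ** -0.5 if rate > 0 else 1.0
        self._b = -self._a * rate * ap if rate > 0 else 0.0
        self._ap = ap

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = self.rng.random(x.shape) >= self.rate
        self._keep = keep
        return self._a * np.where(keep, x, self._ap) + self._b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return dout
        return dout * (self._a * self._keep)


class Sequential:
    """Ordered list of layers with chained forward/backward."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)


def clip_grad_norm(layers: list[Layer], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    sq = 0.0
    for layer in layers:
        for g in layer.grads.values():
            sq += float(np.sum(g * g))
    norm = float(np.sqrt(sq))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for layer in layers:
            for k in layer.grads:
                layer.grads[k] = layer.grads[k] * scale
    return norm


class Adam:
    """Adam optimizer over a list of layers (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, layers: list[Layer], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                self.m[(li, name)] = np.zeros_like(p)
                self.v[(li, name)] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                g = layer.grads[name]
                key = (li, name)
                self.m[key] = b1 * self.m[key] + (1 - b1) * g
                self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
                mhat = self.m[key] / (1 - b1**self.t)
                vhat = self.v[key] / (1 - b2**self.t)
                layer.params[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
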