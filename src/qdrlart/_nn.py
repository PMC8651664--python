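"""Minimal dense neural networks on numpy.

Small fully-connected nets with manual backprop and Adam, sized for
tabular clinical data (5-feature patient states).  Used for the biomarker
transition model, the outcome-estimator mu/T networks, the deep Q-net and
the WGAN-GP critic/generator.  Weights serialize to plain JSON-able dicts
so checkpoints stay text.
"""

from __future__ import annotations

import numpy as np

_ACT = {"relu", "tanh", "linear"}


def _act_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    return z


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0.0).astype(z.dtype)
    if name == "tanh":
        return 1.0 - a * a
    return np.ones_like(z)


class MLP:
    """Fully connected network: ``sizes[0] -> ... -> sizes[-1]``.

    Hidden layers share one activation; the output layer is linear.
    ``forward`` returns a cache that ``backward`` consumes, yielding both
    parameter gradients and the gradient with respect to the input batch.
    """

    def __init__(self, sizes, activation: str = "relu", rng=None):
        if activation not in _ACT:
            raise ValueError(f"unknown activation {activation!r}")
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        rng = np.random.default_rng(rng)
        self.sizes = tuple(int(s) for s in sizes)
        self.activation = activation
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            scale = np.sqrt(2.0 / fan_in) if activation == "relu" else np.sqrt(1.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        zs, acts = [], [X]
        a = X
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            a = z if k == self.n_layers - 1 else _act_forward(self.activation, z)
            acts.append(a)
        return a, (zs, acts)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, cache, grad_out: np.ndarray):
        """Backprop ``grad_out`` (dLoss/dOutput, shape of the output batch).

        Returns ``(grad_W, grad_b, grad_input)``.
        """
        zs, acts = cache
        grad_W = [np.zeros_like(W) for W in self.W]
        grad_b = [np.zeros_like(b) for b in self.b]
        delta = np.atleast_2d(np.asarray(grad_out, dtype=float))
        for k in range(self.n_layers - 1, -1, -1):
            if k != self.n_layers - 1:
                delta = delta * _act_grad(self.activation, zs[k], acts[k + 1])
            grad_W[k] = acts[k].T @ delta
            grad_b[k] = delta.sum(axis=0)
            delta = delta @ self.W[k].T
        return grad_W, grad_b, delta

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """Per-sample gradient of the (scalar) output w.r.t. the input."""
        out, cache = self.forward(X)
        if out.shape[1] != 1:
            raise ValueError("input_gradient requires a scalar-output network")
        _, _, g = self.backward(cache, np.ones_like(out))
        return g

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "activation": self.activation,
            "W": [W.tolist() for W in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        net = cls(d["sizes"], activation=d["activation"], rng=0)
        net.W = [np.asarray(W, dtype=float) for W in d["W"]]
        net.b = [np.asarray(b, dtype=float) for b in d["b"]]
        return net

    def copy(self) -> "MLP":
        return MLP.from_dict(self.to_dict())

    def set_weights_from(self, other: "MLP") -> None:
        self.W = [W.copy() for W in other.W]
        self.b = [b.copy() for b in other.b]


class Adam:
    """Adam optimizer over one MLP's parameters."""

    def __init__(self, net: MLP, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(W) for W in net.W]
        self.vW = [np.zeros_like(W) for W in net.W]
        self.mb = [np.zeros_like(b) for b in net.b]
        self.vb = [np.zeros_like(b) for b in net.b]

    def step(self, grad_W, grad_b) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k in range(self.net.n_layers):
            for param, grad, m, v in (
                (self.net.W[k], grad_W[k], self.mW[k], self.vW[k]),
                (self.net.b[k], grad_b[k], self.mb[k], self.vb[k]),
            ):
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                param -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class Standardizer:
    """Feature-wise z-score transform fitted on a training matrix."""

    def __init__(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)
        self.std[self.std < 1e-12] = 1.0

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        obj = cls.__new__(cls)
        obj.mean = np.asarray(d["mean"], dtype=float)
        obj.std = np.asarray(d["std"], dtype=float)
        return obj
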