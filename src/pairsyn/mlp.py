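"""Minimal deterministic multi-layer perceptron regressor with RAdam.

One hidden ReLU layer by default (the winning configuration for this task),
trained by mini-batch gradient descent on mean-squared error with the
Rectified Adam optimizer.  Written on plain NumPy so that training is
bit-reproducible under a fixed seed on one platform, supports warm starts
from existing weights, and exposes an epoch-0 probe (predictions from the
freshly initialized network before any update).

RAdam (Liu et al.'s rectified variant of Adam) warms up automatically: while
the variance estimate is unreliable (rectification term rho_t <= 4) it takes
plain momentum-SGD steps; afterwards it applies the variance-rectified
adaptive step.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np


@dataclass
class _RAdam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        t = self.t
        b1, b2 = self.beta1, self.beta2
        rho_inf = 2.0 / (1.0 - b2) - 1.0
        beta2_t = b2**t
        rho_t = rho_inf - 2.0 * t * beta2_t / (1.0 - beta2_t)
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**t)
            if rho_t > 4.0:
                v_hat = np.sqrt(self.v[i] / (1 - beta2_t))
                r_t = np.sqrt(
                    ((rho_t - 4) * (rho_t - 2) * rho_inf)
                    / ((rho_inf - 4) * (rho_inf - 2) * rho_t)
                )
                p -= self.lr * r_t * m_hat / (v_hat + self.eps)
            else:
                p -= self.lr * m_hat


class NumpyMLP:
    """Feed-forward ReLU network with a linear scalar output head."""

    def __init__(
        self,
        n_features: int,
        hidden_width: int = 1024,
        hidden_layers: int = 1,
        seed: int = 0,
        dtype=np.float32,
    ):
        if hidden_layers < 1 or hidden_width < 1:
            raise ValueError("hidden_layers and hidden_width must be positive")
        self.n_features = n_features
        self.hidden_width = hidden_width
        self.hidden_layers = hidden_layers
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        dims = [n_features] + [hidden_width] * hidden_layers + [1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / d_in)  # He initialization for ReLU stacks
            self.weights.append(
                (rng.standard_normal((d_in, d_out)) * scale).astype(self.dtype)
            )
            self.biases.append(np.zeros(d_out, dtype=self.dtype))
        self.loss_history: list[float] = []

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return out[:, 0], acts

    def predict(self, X: np.ndarray, batch_size: int = 8192) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=self.dtype)
        outs = [
            self._forward(X[i : i + batch_size])[0]
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(outs) if outs else np.empty(0, dtype=self.dtype)

    def _backward(
        self, acts: list[np.ndarray], out: np.ndarray, y: np.ndarray
    ) -> list[np.ndarray]:
        n = len(y)
        grads_w: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.biases)
        delta = ((out - y) * (2.0 / n)).astype(self.dtype)[:, None]
        grads_w[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        upstream = delta @ self.weights[-1].T
        for layer in range(len(self.weights) - 2, -1, -1):
            upstream = upstream * (acts[layer + 1] > 0)
            grads_w[layer] = acts[layer].T @ upstream
            grads_b[layer] = upstream.sum(axis=0)
            if layer > 0:
                upstream = upstream @ self.weights[layer].T
        return grads_w + grads_b

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        shuffle_seed: int | None = None,
    ) -> "NumpyMLP":
        """Train in place; records mean training MSE per epoch in
        ``loss_history`` (including the epoch-0 loss before any update)."""
        X = np.ascontiguousarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=self.dtype)
        if len(X) == 0:
            raise ValueError("empty training set")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        opt = _RAdam(lr=learning_rate)
        rng = np.random.default_rng(
            self.seed + 1 if shuffle_seed is None else shuffle_seed
        )
        self.loss_history.append(float(np.mean((self.predict(X) - y) ** 2)))
        for _ in range(epochs):
            order = rng.permutation(len(X))
            epoch_loss = 0.0
            for start in range(0, len(X), batch_size):
                idx = order[start : start + batch_size]
                out, acts = self._forward(X[idx])
                epoch_loss += float(np.sum((out - y[idx]) ** 2))
                grads = self._backward(acts, out, y[idx])
                params = self.weights + self.biases
                opt.step(params, grads)
            self.loss_history.append(epoch_loss / len(X))
        return self

    # -- persistence / identity --------------------------------------------

    def state_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "hidden_width": self.hidden_width,
            "hidden_layers": self.hidden_layers,
            "seed": self.seed,
            "dtype": self.dtype.str,
            "weights": [w.copy() for w in self.weights],
            "biases": [b.copy() for b in self.biases],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "NumpyMLP":
        net = cls(
            state["n_features"],
            hidden_width=state["hidden_width"],
            hidden_layers=state["hidden_layers"],
            seed=state["seed"],
            dtype=np.dtype(state["dtype"]),
        )
        net.weights = [np.array(w, dtype=net.dtype) for w in state["weights"]]
        net.biases = [np.array(b, dtype=net.dtype) for b in state["biases"]]
        return net

    def copy(self) -> "NumpyMLP":
        return NumpyMLP.from_state_dict(self.state_dict())

    def load_weights_from(self, other: "NumpyMLP") -> None:
        """Warm start: copy another network's weights (shapes must match)."""
        if (
            other.n_features != self.n_features
            or other.hidden_width != self.hidden_width
            or other.hidden_layers != self.hidden_layers
        ):
            raise ValueError("cannot warm start from a differently shaped network")
        self.weights = [w.copy() for w in other.weights]
        self.biases = [b.copy() for b in other.biases]

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for arr in self.weights + self.biases:
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()
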