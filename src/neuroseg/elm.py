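"""Extreme learning machine: a single-hidden-layer network whose input
weights and biases are random and fixed; only the hidden-to-output
weights are learned, in closed form via the Moore-Penrose pseudoinverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "ELMModel",
    "init_elm",
    "hidden_matrix",
    "moore_penrose_pinv",
    "train_elm",
    "predict",
    "one_hot",
]

ACTIVATIONS = {
    "sigmoid": lambda t: 1.0 / (1.0 + np.exp(-t)),
    "tanh": np.tanh,
    "relu": lambda t: np.maximum(t, 0.0),
}

#: relative singular-value cutoff of the pseudoinverse
PINV_RCOND = 1e-12


@dataclass
class ELMModel:
    W: np.ndarray                      # (H, J) input-to-hidden weights
    k: np.ndarray                      # (H,) hidden biases
    activation: str = "sigmoid"
    beta: np.ndarray | None = None     # (H, O) output weights, set by training
    seed: int | None = None

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "W": self.W.tolist(),
            "k": self.k.tolist(),
            "activation": self.activation,
            "beta": None if self.beta is None else self.beta.tolist(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ELMModel":
        payload = json.loads(Path(path).read_text())
        beta = payload["beta"]
        return cls(
            W=np.asarray(payload["W"], dtype=float),
            k=np.asarray(payload["k"], dtype=float),
            activation=payload["activation"],
            beta=None if beta is None else np.asarray(beta, dtype=float),
            seed=payload["seed"],
        )


def init_elm(
    n_inputs: int,
    n_hidden: int,
    n_outputs: int = 2,
    activation: str = "sigmoid",
    seed: int | None = None,
) -> ELMModel:
    """Draw input weights and biases uniformly from [-1, 1]."""
    if min(n_inputs, n_hidden, n_outputs) < 1:
        raise ValueError("n_inputs, n_hidden and n_outputs must be >= 1")
    if activation not in ACTIVATIONS:
        raise ValueError(
            f"unknown activation {activation!r}; "
            f"supported: {sorted(ACTIVATIONS)}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, n_inputs))
    k = rng.uniform(-1.0, 1.0, size=n_hidden)
    return ELMModel(W=W, k=k, activation=activation, seed=seed)


def hidden_matrix(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output Z with Z[n, i] = b(w_i . x_n + k_i)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"X has {X.shape[1]} columns but model expects {model.n_inputs}")
    act = ACTIVATIONS[model.activation]
    return act(X @ model.W.T + model.k)


def moore_penrose_pinv(Z: np.ndarray) -> np.ndarray:
    """SVD pseudoinverse with singular values below 1e-12 * max zeroed.

    Satisfies the four Penrose conditions to numerical precision.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("matrix contains non-finite entries")
    return np.linalg.pinv(Z, rcond=PINV_RCOND)


def train_elm(model: ELMModel, X: np.ndarray, d: np.ndarray) -> ELMModel:
    """Solve beta = pinv(Z) @ d, the minimum-norm least-squares solution."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = np.atleast_2d(np.asarray(d, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if X.shape[0] != d.shape[0]:
        raise ValueError("X and d row counts differ")
    Z = hidden_matrix(model, X)
    model.beta = moore_penrose_pinv(Z) @ d
    return model


def predict(model: ELMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Network outputs Y = Z beta and argmax class labels (ties -> lowest
    index)."""
    if model.beta is None:
        raise ValueError("model is untrained (beta unset)")
    Z = hidden_matrix(model, X)
    Y = Z @ model.beta
    return Y, np.argmax(Y, axis=1)


def one_hot(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    d = np.zeros((labels.size, n_classes))
    d[np.arange(labels.size), labels] = 1.0
    return d
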