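"""Single-hidden-layer auto-encoder trained by reconstruction-cost descent.

The encoder maps an input vector x (dimension Dx) to a latent vector
z = h1(W1 x + b1) of dimension D1; the decoder maps back with
x_hat = h2(W2 z + b2).  Transfer functions are logistic sigmoids by default
(with a linear option for analytic tests), the cost is the mean squared
error between x and x_hat over all samples and dimensions, and training is
full-batch gradient descent with backtracking: a step that increases the
cost is undone and the learning rate halved, so the best-so-far cost is
monotone non-increasing and training can never diverge silently.

The trained encoder output is the feature table handed to the selector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .table import CategoricalSeries, FeatureTable

__all__ = [
    "AEConfig",
    "AEParams",
    "encode",
    "decode",
    "reconstruction_cost",
    "cost_and_gradients",
    "train",
    "extract_features",
    "save_params",
    "load_params",
]


@dataclass
class AEConfig:
    """Architecture and optimization settings.

    ``input_dim`` (Dx) and ``hidden_dim`` (D1) fix the layer sizes; each
    transfer is ``logistic`` or ``linear``.  ``learning_rate`` is only the
    initial step size — backtracking shrinks it when a step overshoots.
    """

    input_dim: int
    hidden_dim: int
    transfer_encoder: Literal["logistic", "linear"] = "logistic"
    transfer_decoder: Literal["logistic", "linear"] = "logistic"
    epochs: int = 200
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ValueError("input_dim and hidden_dim must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for t in (self.transfer_encoder, self.transfer_decoder):
            if t not in ("logistic", "linear"):
                raise ValueError(f"unknown transfer function: {t!r}")


@dataclass
class AEParams:
    """Weight matrices and bias vectors of encoder (W1, b1) and decoder (W2, b2)."""

    W1: np.ndarray  # D1 x Dx
    b1: np.ndarray  # D1
    W2: np.ndarray  # Dx x D1
    b2: np.ndarray  # Dx

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        d1, dx = self.W1.shape
        if self.b1.shape != (d1,) or self.W2.shape != (dx, d1) or self.b2.shape != (dx,):
            raise ValueError("parameter shapes are inconsistent")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters contain non-finite values")

    def copy(self) -> "AEParams":
        return AEParams(self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())


def _transfer(pre: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-pre))
    return pre


def _transfer_grad(activation: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return activation * (1.0 - activation)
    return np.ones_like(activation)


def _as_matrix(x: np.ndarray, dim: int, name: str) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    was_vector = x.ndim == 1
    if was_vector:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != dim:
        raise ValueError(f"{name} must have {dim} columns, got shape {x.shape}")
    return x, was_vector


def encode(x: np.ndarray, params: AEParams, config: AEConfig) -> np.ndarray:
    """Latent representation z = h1(W1 x + b1); accepts a vector or matrix."""
    X, was_vector = _as_matrix(x, config.input_dim, "x")
    Z = _transfer(X @ params.W1.T + params.b1, config.transfer_encoder)
    return Z[0] if was_vector else Z


def decode(z: np.ndarray, params: AEParams, config: AEConfig) -> np.ndarray:
    """Reconstruction x_hat = h2(W2 z + b2); accepts a vector or matrix."""
    Z, was_vector = _as_matrix(z, config.hidden_dim, "z")
    Xhat = _transfer(Z @ params.W2.T + params.b2, config.transfer_decoder)
    return Xhat[0] if was_vector else Xhat


def reconstruction_cost(X: np.ndarray, params: AEParams, config: AEConfig) -> float:
    """Mean squared error between X and its reconstruction, over all entries."""
    X, _ = _as_matrix(X, config.input_dim, "X")
    if X.shape[0] == 0:
        raise ValueError("cannot compute cost on an empty sample matrix")
    Xhat = decode(encode(X, params, config), params, config)
    return float(np.mean((Xhat - X) ** 2))


def cost_and_gradients(
    X: np.ndarray, params: AEParams, config: AEConfig
) -> tuple[float, AEParams]:
    """Reconstruction cost plus its analytic gradients (as an AEParams bundle)."""
    X, _ = _as_matrix(X, config.input_dim, "X")
    n, dx = X.shape
    if n == 0:
        raise ValueError("cannot compute cost on an empty sample matrix")
    Z = _transfer(X @ params.W1.T + params.b1, config.transfer_encoder)
    Xhat = _transfer(Z @ params.W2.T + params.b2, config.transfer_decoder)
    err = Xhat - X
    cost = float(np.mean(err**2))
    # backprop through mean over n*dx entries
    delta2 = (2.0 / (n * dx)) * err * _transfer_grad(Xhat, config.transfer_decoder)
    gW2 = delta2.T @ Z
    gb2 = delta2.sum(axis=0)
    delta1 = (delta2 @ params.W2) * _transfer_grad(Z, config.transfer_encoder)
    gW1 = delta1.T @ X
    gb1 = delta1.sum(axis=0)
    return cost, AEParams(gW1, gb1, gW2, gb2)


def init_params(config: AEConfig) -> AEParams:
    """Seeded Glorot-uniform initialization (small, symmetric-breaking)."""
    rng = np.random.default_rng(config.seed)
    dx, d1 = config.input_dim, config.hidden_dim
    r1 = np.sqrt(6.0 / (dx + d1))
    W1 = rng.uniform(-r1, r1, size=(d1, dx))
    W2 = rng.uniform(-r1, r1, size=(dx, d1))
    return AEParams(W1, np.zeros(d1), W2, np.zeros(dx))


def train(
    X: np.ndarray, config: AEConfig, return_costs: bool = False
) -> AEParams | tuple[AEParams, list[float]]:
    """Full-batch gradient descent on the reconstruction cost.

    Runs ``config.epochs`` update attempts from a seeded initialization.  A
    step that fails to decrease the cost (or produces a non-finite one) is
    reverted and the learning rate halved; successful steps grow it by 20%,
    so the effective step size adapts to the local gradient scale.  The
    returned parameters always achieve a cost no worse than the initial one.
    Deterministic per seed.
    """
    X, _ = _as_matrix(X, config.input_dim, "X")
    if not np.all(np.isfinite(X)):
        raise ValueError("training data contain non-finite values")
    params = init_params(config)
    cost = reconstruction_cost(X, params, config)
    if not np.isfinite(cost):
        raise FloatingPointError(f"initial reconstruction cost is not finite ({cost})")
    lr = config.learning_rate
    costs = [cost]
    for _ in range(config.epochs):
        _, grads = cost_and_gradients(X, params, config)
        candidate = AEParams(
            params.W1 - lr * grads.W1,
            params.b1 - lr * grads.b1,
            params.W2 - lr * grads.W2,
            params.b2 - lr * grads.b2,
        )
        new_cost = reconstruction_cost(X, candidate, config)
        if np.isfinite(new_cost) and new_cost <= cost:
            params, cost = candidate, new_cost
            lr *= 1.2  # grow the step while descent keeps succeeding
        else:
            lr *= 0.5
            if lr < 1e-12:
                break  # step size exhausted; already at a local plateau
        costs.append(cost)
    if not np.isfinite(cost):
        raise FloatingPointError("training diverged: reconstruction cost is not finite")
    return (params, costs) if return_costs else params


def extract_features(
    X: np.ndarray,
    params: AEParams,
    config: AEConfig,
    y: CategoricalSeries | None = None,
    sample_ids=None,
    class_names=None,
) -> FeatureTable:
    """Encode every sample; latent dimensions become features z0..z(D1-1)."""
    X, _ = _as_matrix(X, config.input_dim, "X")
    Z = encode(X, params, config)
    return FeatureTable(
        X=Z,
        y=y,
        feature_ids=[f"z{j}" for j in range(config.hidden_dim)],
        sample_ids=sample_ids,
        class_names=class_names,
    )


def save_params(params: AEParams, config: AEConfig, path: str | Path) -> None:
    """Serialize weights plus shape/transfer metadata as JSON."""
    payload = {
        "input_dim": config.input_dim,
        "hidden_dim": config.hidden_dim,
        "transfer_encoder": config.transfer_encoder,
        "transfer_decoder": config.transfer_decoder,
        "W1": params.W1.tolist(),
        "b1": params.b1.tolist(),
        "W2": params.W2.tolist(),
        "b2": params.b2.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_params(path: str | Path) -> tuple[AEParams, AEConfig]:
    payload = json.loads(Path(path).read_text())
    config = AEConfig(
        input_dim=payload["input_dim"],
        hidden_dim=payload["hidden_dim"],
        transfer_encoder=payload["transfer_encoder"],
        transfer_decoder=payload["transfer_decoder"],
    )
    params = AEParams(
        np.array(payload["W1"]),
        np.array(payload["b1"]),
        np.array(payload["W2"]),
        np.array(payload["b2"]),
    )
    return params, config
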