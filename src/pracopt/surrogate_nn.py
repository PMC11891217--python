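"""A minimal feedforward regressor trained by error backpropagation.

The surrogate is a single-hidden-layer network (4-h-1 for the extraction
problem): tanh hidden activation, linear output.  Inputs and the response
are min-max scaled to [-1, 1] on the training data before training, and
predictions are inverse-scaled back to percent yield.  Training is plain
full-batch gradient descent on the mean squared error, stopping at the
epoch budget or when the (scaled-space) training MSE drops below the goal.

"Thresholds" in the field's usual phrasing are the bias terms of each layer.
The whole parameter set flattens losslessly to a single vector of length
h*(n_in+1) + n_out*(h+1) (25 for a 4-4-1 network), which is the search
space the metaheuristic trainers operate on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateError",
    "DivergenceError",
    "MinMaxScaler",
    "DataScaler",
    "NetworkParams",
    "TrainConfig",
    "hidden_candidates",
    "forward",
    "train_bp",
    "select_hidden_size",
]


class StateError(RuntimeError):
    """An operation required a fitted scaler that was never fitted."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class MinMaxScaler:
    """Per-column min-max scaling onto [-1, 1].

    Columns with zero range map to 0 (and inverse-map back to the constant),
    so constant features and constant responses are handled gracefully.
    """

    data_min: np.ndarray | None = None
    data_max: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.data_min is not None

    def fit(self, values: np.ndarray) -> "MinMaxScaler":
        V = np.atleast_2d(np.asarray(values, dtype=float))
        self.data_min = V.min(axis=0)
        self.data_max = V.max(axis=0)
        return self

    def _span(self) -> np.ndarray:
        span = self.data_max - self.data_min
        return np.where(span == 0.0, 1.0, span)

    def transform(self, values: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("scaler is not fitted")
        V = np.asarray(values, dtype=float)
        mid = 0.5 * (self.data_min + self.data_max)
        return 2.0 * (V - mid) / self._span()

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("scaler is not fitted")
        V = np.asarray(values, dtype=float)
        mid = 0.5 * (self.data_min + self.data_max)
        return mid + 0.5 * V * self._span()

    def to_dict(self) -> dict:
        return {
            "data_min": None if self.data_min is None else self.data_min.tolist(),
            "data_max": None if self.data_max is None else self.data_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        return cls(
            data_min=None if d["data_min"] is None else np.array(d["data_min"]),
            data_max=None if d["data_max"] is None else np.array(d["data_max"]),
        )


@dataclass
class DataScaler:
    """Paired input/response scalers fitted on the training data only."""

    x: MinMaxScaler = field(default_factory=MinMaxScaler)
    y: MinMaxScaler = field(default_factory=MinMaxScaler)

    @property
    def fitted(self) -> bool:
        return self.x.fitted and self.y.fitted

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DataScaler":
        self.x.fit(X)
        self.y.fit(np.asarray(y, dtype=float).reshape(-1, 1))
        return self

    def to_dict(self) -> dict:
        return {"x": self.x.to_dict(), "y": self.y.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "DataScaler":
        return cls(MinMaxScaler.from_dict(d["x"]), MinMaxScaler.from_dict(d["y"]))


@dataclass
class NetworkParams:
    """Weights and thresholds (biases) of the n_in-h-n_out regressor."""

    input_weights: np.ndarray  # (n_hidden, n_in)
    input_thresholds: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_out, n_hidden)
    output_thresholds: np.ndarray  # (n_out,)
    scaler: DataScaler | None = None

    @property
    def n_in(self) -> int:
        return self.input_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_out(self) -> int:
        return self.output_weights.shape[0]

    @staticmethod
    def n_params(n_in: int, n_hidden: int, n_out: int = 1) -> int:
        return n_hidden * (n_in + 1) + n_out * (n_hidden + 1)

    def flatten(self) -> np.ndarray:
        """Lossless bijection onto a single parameter vector."""
        return np.concatenate(
            [
                self.input_weights.ravel(),
                self.input_thresholds,
                self.output_weights.ravel(),
                self.output_thresholds,
            ]
        )

    @classmethod
    def from_vector(
        cls,
        vec: np.ndarray,
        n_in: int,
        n_hidden: int,
        n_out: int = 1,
        scaler: DataScaler | None = None,
    ) -> "NetworkParams":
        vec = np.asarray(vec, dtype=float)
        expected = cls.n_params(n_in, n_hidden, n_out)
        if vec.shape != (expected,):
            raise ValueError(f"expected parameter vector of length {expected}")
        a = n_hidden * n_in
        b = a + n_hidden
        c = b + n_out * n_hidden
        return cls(
            input_weights=vec[:a].reshape(n_hidden, n_in).copy(),
            input_thresholds=vec[a:b].copy(),
            output_weights=vec[b:c].reshape(n_out, n_hidden).copy(),
            output_thresholds=vec[c:].copy(),
            scaler=scaler,
        )

    def to_dict(self) -> dict:
        return {
            "layout": [self.n_in, self.n_hidden, self.n_out],
            "vector": self.flatten().tolist(),
            "scaler": None if self.scaler is None else self.scaler.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        n_in, n_hidden, n_out = d["layout"]
        scaler = None if d.get("scaler") is None else DataScaler.from_dict(d["scaler"])
        return cls.from_vector(np.array(d["vector"]), n_in, n_hidden, n_out, scaler)


@dataclass(frozen=True)
class TrainConfig:
    """Backpropagation budget and stopping rule.

    ``goal_mse`` applies to the scaled-space training MSE, matching the
    published stopping target of 1e-5 on the training error.
    """

    max_epochs: int = 1000
    goal_mse: float = 1e-5
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.goal_mse <= 0:
            raise ValueError("goal_mse must be positive")


def hidden_candidates(n_in: int, n_out: int) -> list[int]:
    """Candidate hidden-layer sizes: round(sqrt(n_in + n_out)) + a, a = 1..10."""
    if n_in < 1 or n_out < 1:
        raise ValueError("layer sizes must be >= 1")
    base = round(math.sqrt(n_in + n_out))
    return sorted({base + a for a in range(1, 11)})


def _forward_scaled(params: NetworkParams, Xs: np.ndarray) -> np.ndarray:
    """Network output in scaled space; Xs is (n, n_in), result (n, n_out)."""
    hidden = np.tanh(Xs @ params.input_weights.T + params.input_thresholds)
    return hidden @ params.output_weights.T + params.output_thresholds


def forward(
    params: NetworkParams, x: np.ndarray, scaler: DataScaler | None = None
) -> float | np.ndarray:
    """Predict the response (in actual units) at one point or a batch."""
    scaler = scaler if scaler is not None else params.scaler
    if scaler is None or not scaler.fitted:
        raise StateError("forward requires a fitted scaler")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xs = scaler.x.transform(np.atleast_2d(x))
    out = scaler.y.inverse_transform(_forward_scaled(params, Xs))
    return float(out[0, 0]) if single else out[:, 0]


def scaled_mse(params: NetworkParams, Xs: np.ndarray, ys: np.ndarray) -> float:
    """Training objective: MSE between scaled targets and network output."""
    err = _forward_scaled(params, Xs)[:, 0] - ys
    return float(np.mean(err**2))


def _init_params(
    n_in: int, h: int, rng: np.random.Generator, scaler: DataScaler
) -> NetworkParams:
    vec = rng.uniform(-0.5, 0.5, NetworkParams.n_params(n_in, h))
    return NetworkParams.from_vector(vec, n_in, h, scaler=scaler)


def train_bp(
    data: tuple[np.ndarray, np.ndarray],
    h: int,
    config: TrainConfig | None = None,
    init: NetworkParams | None = None,
) -> tuple[NetworkParams, list[float]]:
    """Train by full-batch gradient descent on the MSE.

    Returns the best parameters seen during training (so the final training
    MSE can never exceed the initial one) and the per-epoch MSE history;
    ``history[0]`` is the MSE of the initial weights.  Identical seeds give
    bitwise-identical histories.
    """
    config = config or TrainConfig()
    X, y = (np.asarray(a, dtype=float) for a in data)
    if len(X) < 2:
        raise ValueError("need at least 2 training samples")
    if h < 1:
        raise ValueError("hidden size must be >= 1")
    scaler = DataScaler().fit(X, y)
    Xs = scaler.x.transform(X)
    ys = scaler.y.transform(y.reshape(-1, 1))[:, 0]
    n = len(Xs)
    rng = np.random.default_rng(config.seed)
    if init is not None:
        params = NetworkParams.from_vector(
            init.flatten(), init.n_in, init.n_hidden, init.n_out, scaler
        )
    else:
        params = _init_params(X.shape[1], h, rng, scaler)

    W1 = params.input_weights
    b1 = params.input_thresholds
    W2 = params.output_weights
    b2 = params.output_thresholds
    lr = config.learning_rate

    def current_mse() -> float:
        with np.errstate(over="ignore"):  # overflow -> inf -> DivergenceError
            err = (np.tanh(Xs @ W1.T + b1) @ W2.T + b2)[:, 0] - ys
            return float(np.mean(err**2))

    mse = current_mse()
    history = [mse]
    best_mse = mse
    best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
    for _ in range(config.max_epochs):
        if mse < config.goal_mse:
            break
        hidden = np.tanh(Xs @ W1.T + b1)  # (n, h)
        out = hidden @ W2.T + b2  # (n, 1)
        err = out[:, 0] - ys
        delta_out = (2.0 / n) * err[:, None]  # (n, 1)
        gW2 = delta_out.T @ hidden
        gb2 = delta_out.sum(axis=0)
        delta_hid = (delta_out @ W2) * (1.0 - hidden**2)  # (n, h)
        gW1 = delta_hid.T @ Xs
        gb1 = delta_hid.sum(axis=0)
        W1 -= lr * gW1
        b1 -= lr * gb1
        W2 -= lr * gW2
        b2 -= lr * gb2
        mse = current_mse()
        if not np.isfinite(mse):
            raise DivergenceError(
                "training loss became non-finite; try a smaller learning_rate"
            )
        history.append(mse)
        if mse < best_mse:
            best_mse = mse
            best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())

    result = NetworkParams(*[a.copy() for a in best], scaler=scaler)
    return result, history


def select_hidden_size(
    data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    candidates: list[int] | None = None,
) -> int:
    """Pick the hidden size minimizing training MSE (ties to the smaller h)."""
    config = config or TrainConfig()
    X, _ = data
    if candidates is None:
        candidates = hidden_candidates(np.asarray(X).shape[1], 1)
    if not candidates:
        raise ValueError("candidate list is empty")
    best_h, best_mse = None, np.inf
    for h in sorted(candidates):
        _, history = train_bp(data, h, config)
        final = min(history)
        if final < best_mse:
            best_h, best_mse = h, final
    return best_h
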