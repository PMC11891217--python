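"""Goodness-of-fit metrics, data splitting, and the four-model comparison.

R² is the standard coefficient of determination 1 - RSS/TSS computed
against the actual responses (it may be negative for a model worse than the
mean); MAE and RMSE are the usual absolute and quadratic mean errors.  The
published comparison of the four extraction-yield models is computed over
all 29 design runs — training rows included — which is the basis that
reproduces the published table, so ``basis="all"`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import MODEL_NAMES, DesignTable, PaperFixture

__all__ = [
    "ModelMetrics",
    "MetricsReport",
    "mae",
    "rmse",
    "r2",
    "compare_models",
    "split",
]


def _paired(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1 or a.size == 0:
        raise ValueError(
            f"actual and predicted must be equal-length nonempty vectors, "
            f"got shapes {a.shape} and {p.shape}"
        )
    return a, p


def mae(actual, predicted) -> float:
    """Mean absolute error."""
    a, p = _paired(actual, predicted)
    return float(np.mean(np.abs(a - p)))


def rmse(actual, predicted) -> float:
    """Root mean squared error."""
    a, p = _paired(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r2(actual, predicted) -> float:
    """Coefficient of determination, 1 - RSS/TSS.

    Undefined (raises) when the actual values are all equal, since TSS = 0.
    """
    a, p = _paired(actual, predicted)
    tss = float(np.sum((a - a.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("r2 is undefined for a constant actual vector")
    return 1.0 - float(np.sum((a - p) ** 2)) / tss


@dataclass(frozen=True)
class ModelMetrics:
    r2: float
    mae: float
    rmse: float


@dataclass
class MetricsReport:
    """Per-model metrics over a common evaluation basis."""

    metrics: dict[str, ModelMetrics]
    n: int
    basis: str = "all"

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped view: one row per model, columns model/r2/mae/rmse."""
        return pd.DataFrame(
            [
                {"model": name, "r2": m.r2, "mae": m.mae, "rmse": m.rmse}
                for name, m in self.metrics.items()
            ]
        )


def compare_models(fixture: PaperFixture, basis: str = "all") -> MetricsReport:
    """R²/MAE/RMSE of each prediction column against the actual yields."""
    if basis != "all":
        raise ValueError("only basis='all' is supported for the packaged fixture")
    actual = fixture.design.y
    metrics = {}
    for name in MODEL_NAMES:
        if name not in fixture.predicted:
            raise KeyError(f"fixture has no predictions for model {name!r}")
        pred = fixture.predicted[name]
        metrics[name] = ModelMetrics(
            r2=r2(actual, pred), mae=mae(actual, pred), rmse=rmse(actual, pred)
        )
    return MetricsReport(metrics=metrics, n=len(actual), basis=basis)


def split(
    table: DesignTable, n_train: int, seed: int
) -> tuple[DesignTable, DesignTable]:
    """Seeded uniform train/test split without replacement.

    The parts are disjoint and exhaustive; within each part the original
    run order is preserved.  The published protocol used 21 training and
    8 test rows of the 29-run design (row assignment unpublished).
    """
    n = len(table)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must lie strictly between 0 and {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = sorted(perm[:n_train].tolist())
    test_idx = sorted(perm[n_train:].tolist())
    return table.subset(train_idx), table.subset(test_idx)
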