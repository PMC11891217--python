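"""Domain types and I/O for designed extraction experiments.

The central object is the :class:`DesignTable`: the factor settings and the
measured response (polysaccharide yield, in percent of plant dry mass) for
each run of a designed experiment.  The packaged dataset is a 29-run,
four-factor, three-level Box-Behnken design for microwave-assisted extraction
of polysaccharides from *Radix Actinidiae Chinensis* (PRAC), together with
the per-run predictions of four fitted models (quadratic response surface and
three neural surrogates).

Responses are always stored as percent (4.170 means a 4.170 % yield), never
as fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "CodingError",
    "FactorSpec",
    "DesignRun",
    "DesignTable",
    "PaperFixture",
    "MODEL_NAMES",
    "load_design",
    "to_coded",
    "from_coded",
    "paper_factors",
    "paper_dataset",
]

#: Names of the four compared models, in presentation order.
MODEL_NAMES = ("box-behnken", "bp", "ga-bp", "ga-aco-bp")

_LEVEL_TOL = 1e-9


class SchemaError(ValueError):
    """A design CSV is structurally invalid (missing/duplicate columns)."""


class ParseError(ValueError):
    """A design CSV contains a non-numeric cell where a number is required."""


class CodingError(ValueError):
    """A factor setting does not sit on one of its three declared levels."""


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its three levels in actual units.

    A three-level response-surface factor is symmetric: the center level is
    the midpoint of the low and high levels, so that the coded values
    (-1, 0, +1) map affinely onto actual units.
    """

    name: str
    unit: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got ({self.low}, {self.center}, {self.high})"
            )
        if abs(self.center - 0.5 * (self.low + self.high)) > _LEVEL_TOL:
            raise ValueError(
                f"factor {self.name!r}: center must be the midpoint of low and high"
            )

    @property
    def levels(self) -> tuple[float, float, float]:
        return (self.low, self.center, self.high)

    @property
    def half_width(self) -> float:
        """Distance from center to either outer level (the coding scale)."""
        return 0.5 * (self.high - self.low)

    def code(self, value: float) -> float:
        """Map an on-level actual value to -1 / 0 / +1."""
        for coded, level in zip((-1.0, 0.0, 1.0), self.levels):
            if abs(value - level) <= _LEVEL_TOL * max(1.0, abs(level)):
                return coded
        raise CodingError(
            f"factor {self.name!r}: value {value} is not one of the levels {self.levels}"
        )

    def decode(self, coded: float) -> float:
        """Map a coded value back to actual units (exact affine inverse)."""
        return self.center + coded * self.half_width


@dataclass(frozen=True)
class DesignRun:
    """A single experimental run: identifier, settings, optional response."""

    run_id: int
    settings: tuple[float, ...]
    response: float | None = None


@dataclass
class DesignTable:
    """Factor settings and responses for a designed experiment."""

    factors: list[FactorSpec]
    runs: list[DesignRun]

    def __post_init__(self) -> None:
        k = len(self.factors)
        for run in self.runs:
            if len(run.settings) != k:
                raise SchemaError(
                    f"run {run.run_id}: expected {k} settings, got {len(run.settings)}"
                )

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def X(self) -> np.ndarray:
        """(n, k) matrix of settings in actual units."""
        return np.array([run.settings for run in self.runs], dtype=float)

    @property
    def has_responses(self) -> bool:
        return all(run.response is not None for run in self.runs)

    @property
    def y(self) -> np.ndarray:
        """(n,) response vector; raises if any response is missing."""
        if not self.has_responses:
            missing = [r.run_id for r in self.runs if r.response is None]
            raise ValueError(f"responses missing for runs {missing}")
        return np.array([run.response for run in self.runs], dtype=float)

    def is_center_run(self, run: DesignRun) -> bool:
        return all(
            abs(s - f.center) <= _LEVEL_TOL * max(1.0, abs(f.center))
            for s, f in zip(run.settings, self.factors)
        )

    @property
    def center_run_ids(self) -> list[int]:
        return [r.run_id for r in self.runs if self.is_center_run(r)]

    @property
    def n_center(self) -> int:
        return len(self.center_run_ids)

    def with_responses(self, responses: Sequence[float]) -> "DesignTable":
        if len(responses) != len(self.runs):
            raise ValueError("response vector length does not match run count")
        return DesignTable(
            self.factors,
            [
                DesignRun(r.run_id, r.settings, float(v))
                for r, v in zip(self.runs, responses)
            ],
        )

    def subset(self, indices: Sequence[int]) -> "DesignTable":
        """Rows at the given positional indices, order preserved."""
        return DesignTable(self.factors, [self.runs[i] for i in indices])


@dataclass
class PaperFixture:
    """The published 29-run dataset plus the four models' per-run predictions."""

    design: DesignTable
    predicted: Mapping[str, np.ndarray] = field(default_factory=dict)


def to_coded(table: DesignTable) -> np.ndarray:
    """Code every setting of a three-level table to -1 / 0 / +1.

    Raises :class:`CodingError` if any setting is off-level.  The inverse
    transform (:func:`from_coded`) restores actual units exactly.
    """
    X = table.X
    Z = np.empty_like(X)
    for j, factor in enumerate(table.factors):
        for i in range(X.shape[0]):
            Z[i, j] = factor.code(X[i, j])
    return Z


def from_coded(factors: Sequence[FactorSpec], Z: np.ndarray) -> np.ndarray:
    """Map coded settings back to actual units."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_width for f in factors])
    return centers + Z * halves


def _factor_from_column(name: str, values: np.ndarray) -> FactorSpec:
    """Infer a three-level FactorSpec from a data column.

    Column headers of the form ``name_unit`` (e.g. ``temperature_C``,
    ``ratio_mL_per_g``) carry the unit after the first underscore.
    """
    levels = np.unique(values)
    if len(levels) != 3:
        raise SchemaError(
            f"column {name!r}: expected exactly 3 distinct levels for a "
            f"Box-Behnken factor, found {len(levels)}"
        )
    low, center, high = (float(v) for v in levels)
    if abs(center - 0.5 * (low + high)) > 1e-9 * max(1.0, abs(high)):
        raise SchemaError(
            f"column {name!r}: middle level {center} is not the midpoint of "
            f"({low}, {high})"
        )
    base, _, unit = name.partition("_")
    return FactorSpec(name=base or name, unit=unit, low=low, center=center, high=high)


def load_design(
    path: str | Path,
    response: str = "yield_pct",
    factors: Sequence[FactorSpec] | None = None,
) -> DesignTable:
    """Read a design CSV (``run``, factor columns, optional response column).

    The header row is mandatory: one ``run`` column, one column per factor,
    and optionally a response column named *response*.  Factor levels are
    inferred from the data unless *factors* is given explicitly.  Row order
    is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header row") from exc
    df.columns = [c.strip() for c in df.columns]
    if "run" not in df.columns:
        raise SchemaError(f"{path}: missing required 'run' column")
    factor_cols = [c for c in df.columns if c not in ("run", response)]
    if not factor_cols:
        raise SchemaError(f"{path}: no factor columns found")

    def _numeric(col: str) -> np.ndarray:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() & raw.notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {raw.iloc[i]!r} in column {col!r}, "
                f"data row {i + 1}"
            )
        return out.to_numpy(dtype=float)

    run_ids = _numeric("run")
    Xcols = {c: _numeric(c) for c in factor_cols}
    if factors is None:
        factors = [_factor_from_column(c, v) for c, v in Xcols.items()]
    elif len(factors) != len(factor_cols):
        raise SchemaError(
            f"{path}: {len(factor_cols)} factor columns but {len(factors)} "
            "factor specs supplied"
        )
    responses: list[float | None]
    if response in df.columns:
        yvals = _numeric(response)
        responses = [None if np.isnan(v) else float(v) for v in yvals]
    else:
        responses = [None] * len(df)
    X = np.column_stack([Xcols[c] for c in factor_cols])
    runs = [
        DesignRun(int(run_ids[i]), tuple(X[i]), responses[i]) for i in range(len(df))
    ]
    return DesignTable(list(factors), runs)


def paper_factors() -> list[FactorSpec]:
    """The four microwave-extraction factors with their published levels.

    A: liquid-to-solid ratio (mL/g), B: extraction temperature (deg C),
    C: extraction time (min), D: microwave power (W).
    """
    return [
        FactorSpec("ratio", "mL/g", 14.0, 18.0, 22.0),
        FactorSpec("temperature", "degC", 60.0, 80.0, 100.0),
        FactorSpec("time", "min", 60.0, 90.0, 120.0),
        FactorSpec("power", "W", 300.0, 400.0, 500.0),
    ]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pracopt").joinpath("data", name)))


def paper_dataset() -> PaperFixture:
    """The packaged 29-run dataset with the four models' predictions.

    The five center replicates are the runs with all factors at
    (18 mL/g, 80 degC, 90 min, 400 W).  Actual yields span 2.149-4.170 %.
    """
    design = load_design(_data_path("prac_bbd29.csv"), factors=paper_factors())
    preds = pd.read_csv(_data_path("prac_bbd29_predictions.csv"))
    predicted = {
        "box-behnken": preds["pred_bbd"].to_numpy(dtype=float),
        "bp": preds["pred_bp"].to_numpy(dtype=float),
        "ga-bp": preds["pred_gabp"].to_numpy(dtype=float),
        "ga-aco-bp": preds["pred_gaacobp"].to_numpy(dtype=float),
    }
    return PaperFixture(design=design, predicted=predicted)
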