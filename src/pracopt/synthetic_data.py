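"""Synthetic Box-Behnken experiments with a known response surface.

The generator emulates the data-generating assumption behind a response-
surface experiment: a smooth (here quadratic, optionally perturbed) yield
surface plus i.i.d. Gaussian replicate noise.  The default "paper-like"
surface uses the published quadratic coefficients with noise equal to the
residual scatter of the published fit (sd = sqrt(0.058) ~ 0.24 percentage
points of yield); the pure replicate scatter at the center corresponds to
sd ~ sqrt(0.0131) ~ 0.11.

Run order is deterministic (pair-lexicographic edge runs, then center
replicates) so tables are reproducible byte-for-byte; the randomized run
order a DoE package would emit is deliberately not simulated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core_data import DesignRun, DesignTable, FactorSpec, to_coded
from .rsm import QuadraticModel, published_yield_model

__all__ = [
    "Perturbation",
    "SurfaceSpec",
    "generate_bbd",
    "simulate_response",
    "paper_like_spec",
    "PAPER_RESIDUAL_SD",
]

#: Residual standard deviation of the published quadratic fit, sqrt(0.058).
PAPER_RESIDUAL_SD = math.sqrt(0.058)


@dataclass(frozen=True)
class Perturbation:
    """A smooth non-quadratic term added to the true surface.

    Evaluated in coded units as amplitude * sin(1.5*z_i) * sin(1.5*z_j) for
    the chosen factor pair; the frequency keeps the term non-polynomial yet
    non-zero at the design points.
    """

    amplitude: float
    factor_pair: tuple[int, int]

    def evaluate(self, Z: np.ndarray) -> np.ndarray:
        i, j = self.factor_pair
        return self.amplitude * np.sin(1.5 * Z[:, i]) * np.sin(1.5 * Z[:, j])


@dataclass(frozen=True)
class SurfaceSpec:
    """True surface + noise level defining a simulated experiment."""

    true_model: QuadraticModel
    noise_sd: float
    perturbation: Perturbation | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_bbd(factors: list[FactorSpec], n_center: int) -> DesignTable:
    """A three-level Box-Behnken design for 3-7 factors.

    All 4*C(k,2) edge runs (one factor pair at +/-1, the rest at center)
    in pair-lexicographic order, followed by ``n_center`` center replicates.
    Responses are left absent.
    """
    k = len(factors)
    if not 3 <= k <= 7:
        raise ValueError(f"Box-Behnken construction supports 3-7 factors, got {k}")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_width for f in factors])
    rows: list[np.ndarray] = []
    for i, j in itertools.combinations(range(k), 2):
        for zi, zj in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
            z = np.zeros(k)
            z[i], z[j] = zi, zj
            rows.append(centers + z * halves)
    rows.extend(centers.copy() for _ in range(n_center))
    runs = [
        DesignRun(run_id=i + 1, settings=tuple(row)) for i, row in enumerate(rows)
    ]
    return DesignTable(list(factors), runs)


def simulate_response(
    design: DesignTable, spec: SurfaceSpec, seed: int
) -> DesignTable:
    """Evaluate the true surface on the design and add Gaussian noise."""
    model = spec.true_model.to_units("actual")
    mean = np.asarray(model.predict(design.X), dtype=float)
    if spec.perturbation is not None:
        mean = mean + spec.perturbation.evaluate(to_coded(design))
    rng = np.random.default_rng(seed)
    y = mean + rng.normal(0.0, spec.noise_sd, size=len(design))
    return design.with_responses(y)


def paper_like_spec(
    noise_sd: float = PAPER_RESIDUAL_SD,
    perturbation: Perturbation | None = None,
) -> SurfaceSpec:
    """The published yield surface with its fitted residual noise level."""
    return SurfaceSpec(
        true_model=published_yield_model(),
        noise_sd=noise_sd,
        perturbation=perturbation,
    )
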