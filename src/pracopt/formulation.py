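"""Assay formulas and first-order release kinetics for the liposome work.

The closed-form assays are mass-balance percentages: extraction yield,
polysaccharide purity, liposome encapsulation efficiency (EE) and loading
capacity (LC), and the colloidal stability coefficient Ke (relative
absorbance drop after centrifugation).

Cumulative *in vitro* release follows first-order kinetics,

    M(t) = M_inf * (1 - exp(-k t)),

with plateau M_inf in percent cumulative release and rate k per hour.  The
published fits are M(t) = 93.47*(1-e^(-0.30 t)) at gastric pH 2 and
M(t) = 90.68*(1-e^(-0.24 t)) at intestinal pH 7.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize

__all__ = [
    "DomainError",
    "ReleaseModel",
    "yield_pct",
    "purity_pct",
    "ee_pct",
    "lc_pct",
    "ke",
    "release_curve",
    "fit_release",
]


class DomainError(ValueError):
    """An assay formula was called outside its physical domain."""


def _check_nonneg(**masses: float) -> None:
    for name, v in masses.items():
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")


def yield_pct(w_material: float, w_extract: float) -> float:
    """Extraction yield: dried extract mass over raw material mass, in %."""
    _check_nonneg(w_material=w_material, w_extract=w_extract)
    if w_material == 0:
        raise DomainError("raw material mass must be positive")
    return 100.0 * w_extract / w_material


def purity_pct(w_extract: float, w_polysaccharide: float) -> float:
    """Polysaccharide purity: assayed sugar mass over extract mass, in %."""
    _check_nonneg(w_extract=w_extract, w_polysaccharide=w_polysaccharide)
    if w_extract == 0:
        raise DomainError("extract mass must be positive")
    return 100.0 * w_polysaccharide / w_extract


def ee_pct(w_free: float, w_total: float) -> float:
    """Encapsulation efficiency: entrapped over total polysaccharide, in %."""
    _check_nonneg(w_free=w_free, w_total=w_total)
    if w_total == 0:
        raise DomainError("total polysaccharide mass must be positive")
    return 100.0 * (w_total - w_free) / w_total


def lc_pct(w_free: float, w_total: float, w_carrier: float) -> float:
    """Loading capacity: entrapped polysaccharide over carrier + drug, in %."""
    _check_nonneg(w_free=w_free, w_total=w_total, w_carrier=w_carrier)
    if w_carrier + w_total == 0:
        raise DomainError("carrier + polysaccharide mass must be positive")
    return 100.0 * (w_total - w_free) / (w_carrier + w_total)


def ke(a0: float, a: float) -> float:
    """Stability coefficient: relative absorbance drop after centrifugation."""
    if a0 <= 0:
        raise DomainError("initial absorbance must be positive")
    return (a0 - a) / a0


@dataclass(frozen=True)
class ReleaseModel:
    """First-order release: plateau m_inf (% cumulative) and rate k (1/h)."""

    m_inf: float
    k: float
    r2: float = float("nan")
    quality_warning: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.m_inf <= 100.0:
            raise ValueError(f"m_inf must lie in (0, 100], got {self.m_inf}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")


def release_curve(model: ReleaseModel, t) -> float | np.ndarray:
    """Cumulative release (%) at time(s) t >= 0 hours."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    out = model.m_inf * (1.0 - np.exp(-model.k * t_arr))
    return float(out) if np.isscalar(t) else out


def _initial_guess(t: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    m0 = max(float(m.max()), 1e-6)
    # rate from the first informative point: m = m0*(1 - e^(-k t))
    k0 = 0.3
    for ti, mi in zip(t, m):
        if ti > 0 and 0 < mi < m0:
            k0 = -np.log(1.0 - mi / (m0 * 1.0001)) / ti
            break
    return min(m0, 100.0), float(np.clip(k0, 1e-3, 10.0))


def fit_release(times, cumrel) -> ReleaseModel:
    """Nonlinear least-squares fit of the first-order release model.

    Requires at least 3 points including an early (t <= 1 h) sample so the
    rate is identifiable.  Data that are not predominantly nondecreasing
    are still fitted, but the returned model carries a quality warning.
    """
    t = np.asarray(times, dtype=float)
    m = np.asarray(cumrel, dtype=float)
    if t.shape != m.shape or t.ndim != 1:
        raise ValueError("times and cumrel must be equal-length vectors")
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(t < 0):
        raise DomainError("times must be >= 0")
    if t.min() > 1.0:
        raise ValueError("need an early sample (t <= 1 h) to pin down the rate")

    order = np.argsort(t)
    t, m = t[order], m[order]
    diffs = np.diff(m)
    frac_nondecreasing = float(np.mean(diffs >= 0)) if len(diffs) else 1.0
    warning = None
    if frac_nondecreasing < 0.6:
        warning = (
            f"cumulative release is not monotone-dominant "
            f"({frac_nondecreasing:.0%} of steps nondecreasing)"
        )
        warnings.warn(warning, stacklevel=2)

    def curve(tt, m_inf, k):
        return m_inf * (1.0 - np.exp(-k * tt))

    p0 = _initial_guess(t, m)
    popt, _ = scipy.optimize.curve_fit(
        curve, t, m, p0=p0, bounds=([1e-6, 1e-6], [100.0, 10.0]), maxfev=10000
    )
    m_inf, k = (float(v) for v in popt)
    resid = m - curve(t, m_inf, k)
    tss = float(np.sum((m - m.mean()) ** 2))
    fit_r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else float("nan")
    return ReleaseModel(m_inf=m_inf, k=k, r2=fit_r2, quality_warning=warning)
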