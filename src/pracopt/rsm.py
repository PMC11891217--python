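"""Second-order response-surface fit, ANOVA, PRESS and surface optimization.

The response surface is the full quadratic in k factors,

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2,

fitted by ordinary least squares (15 terms for the four-factor extraction
design).  The ANOVA partitions the corrected total sum of squares into
per-term (Type-III) contributions, residual, lack-of-fit and pure error,
with pure error estimated from replicated runs (the five center replicates
in the packaged design).

Per-term sums of squares are always computed on the coded (-1, 0, +1) basis,
the convention of standard DoE software: Type-III SS of lower-order terms is
not invariant under affine reparameterization, and the coded basis is the one
under which a Box-Behnken design is (near-)orthogonal.  The model object
itself may carry coefficients in either unit system; conversion between the
two is exact.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .core_data import DesignTable, FactorSpec, paper_factors, to_coded

__all__ = [
    "SingularDesignError",
    "LeverageError",
    "QuadraticModel",
    "AnovaRow",
    "AnovaTable",
    "term_names",
    "quadratic_design_matrix",
    "fit_quadratic",
    "predict",
    "anova",
    "press_and_predicted_r2",
    "optimize_surface",
    "published_yield_model",
]


class SingularDesignError(ValueError):
    """The quadratic basis is rank-deficient on the given design."""


class LeverageError(ValueError):
    """A run has leverage 1; its leave-one-out residual is undefined."""


_FACTOR_LETTERS = "ABCDEFG"


def term_names(k: int) -> list[str]:
    """Names of the 1 + k + k(k-1)/2 + k quadratic-basis terms, in order."""
    letters = _FACTOR_LETTERS[:k]
    names = ["Intercept"]
    names += list(letters)
    names += [a + b for a, b in itertools.combinations(letters, 2)]
    names += [a + "²" for a in letters]
    return names


def quadratic_design_matrix(X: np.ndarray) -> np.ndarray:
    """Expand (n, k) settings into the full second-order basis (n, n_terms)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class QuadraticModel:
    """A full second-order polynomial over k factors.

    ``interaction`` is ordered by factor-pair lexicographically:
    (0,1), (0,2), ..., (k-2,k-1) -- AB, AC, AD, BC, BD, CD for k = 4.
    ``units`` says whether the coefficients act on actual-unit settings or
    on coded (-1, 0, +1) settings.
    """

    intercept: float
    linear: tuple[float, ...]
    interaction: tuple[float, ...]
    quadratic: tuple[float, ...]
    units: str
    factors: tuple[FactorSpec, ...]

    def __post_init__(self) -> None:
        k = len(self.linear)
        if self.units not in ("actual", "coded"):
            raise ValueError(f"units must be 'actual' or 'coded', got {self.units!r}")
        if len(self.quadratic) != k or len(self.interaction) != k * (k - 1) // 2:
            raise ValueError("inconsistent coefficient block lengths")
        if len(self.factors) != k:
            raise ValueError("factor list length does not match coefficients")

    @property
    def k(self) -> int:
        return len(self.linear)

    @property
    def coefficients(self) -> np.ndarray:
        """All coefficients as one vector, in design-matrix column order."""
        return np.concatenate(
            [[self.intercept], self.linear, self.interaction, self.quadratic]
        )

    @classmethod
    def from_coefficients(
        cls,
        beta: np.ndarray,
        units: str,
        factors: tuple[FactorSpec, ...],
    ) -> "QuadraticModel":
        k = len(factors)
        n_int = k * (k - 1) // 2
        beta = np.asarray(beta, dtype=float)
        return cls(
            intercept=float(beta[0]),
            linear=tuple(beta[1 : 1 + k]),
            interaction=tuple(beta[1 + k : 1 + k + n_int]),
            quadratic=tuple(beta[1 + k + n_int :]),
            units=units,
            factors=tuple(factors),
        )

    def predict(self, settings: np.ndarray) -> float | np.ndarray:
        """Evaluate the polynomial at one point (k,) or a batch (n, k)."""
        settings = np.asarray(settings, dtype=float)
        single = settings.ndim == 1
        Z = quadratic_design_matrix(settings)
        out = Z @ self.coefficients
        return float(out[0]) if single else out

    def gradient(self, settings: np.ndarray) -> np.ndarray:
        """Analytic gradient at a single point (k,)."""
        x = np.asarray(settings, dtype=float)
        k = self.k
        g = np.array(self.linear) + 2.0 * np.array(self.quadratic) * x
        for idx, (i, j) in enumerate(itertools.combinations(range(k), 2)):
            g[i] += self.interaction[idx] * x[j]
            g[j] += self.interaction[idx] * x[i]
        return g

    def _affine_substitute(
        self, offsets: np.ndarray, scales: np.ndarray, new_units: str
    ) -> "QuadraticModel":
        """Re-express the polynomial under x_old = offsets + scales * x_new."""
        k = self.k
        b0 = self.intercept
        b = np.array(self.linear)
        bq = np.array(self.quadratic)
        pairs = list(itertools.combinations(range(k), 2))
        B = np.zeros((k, k))  # symmetric interaction matrix, zero diagonal
        for idx, (i, j) in enumerate(pairs):
            B[i, j] = B[j, i] = self.interaction[idx]
        c, h = offsets, scales
        g0 = b0 + b @ c + 0.5 * c @ B @ c + bq @ (c**2)
        g_lin = h * (b + B @ c + 2.0 * bq * c)
        g_int = tuple(B[i, j] * h[i] * h[j] for i, j in pairs)
        g_quad = bq * h**2
        return QuadraticModel(
            intercept=float(g0),
            linear=tuple(g_lin),
            interaction=g_int,
            quadratic=tuple(g_quad),
            units=new_units,
            factors=self.factors,
        )

    def to_units(self, units: str) -> "QuadraticModel":
        """Exact conversion between actual-unit and coded coefficients."""
        if units == self.units:
            return self
        centers = np.array([f.center for f in self.factors])
        halves = np.array([f.half_width for f in self.factors])
        if units == "coded":  # actual(x) = c + h * coded(z)
            return self._affine_substitute(centers, halves, "coded")
        if units == "actual":  # coded(z) = -c/h + (1/h) * actual(x)
            return self._affine_substitute(-centers / halves, 1.0 / halves, "actual")
        raise ValueError(f"unknown unit system {units!r}")


def predict(model: QuadraticModel, settings: np.ndarray) -> float | np.ndarray:
    """Functional alias for :meth:`QuadraticModel.predict`."""
    return model.predict(settings)


def _settings_matrix(table: DesignTable, units: str) -> np.ndarray:
    if units == "coded":
        return to_coded(table)
    if units == "actual":
        return table.X
    raise ValueError(f"unknown unit system {units!r}")


def _check_rank(Z: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # QR with column pivoting: the trailing pivots are the dependent terms
        _, _, piv = scipy.linalg.qr(Z, pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise SingularDesignError(
            f"design is rank-deficient (rank {rank} < {Z.shape[1]}); "
            f"collinear terms: {', '.join(bad)}"
        )


def fit_quadratic(table: DesignTable, units: str = "actual") -> QuadraticModel:
    """Ordinary least squares over the full second-order basis.

    Requires at least as many runs as basis terms (15 for four factors).
    """
    y = table.y
    names = term_names(table.k)
    n_terms = len(names)
    if len(table) < n_terms:
        raise ValueError(
            f"need at least {n_terms} runs to fit {n_terms} terms, got {len(table)}"
        )
    Z = quadratic_design_matrix(_settings_matrix(table, units))
    _check_rank(Z, names)
    res = sm.OLS(y, Z).fit()
    return QuadraticModel.from_coefficients(res.params, units, tuple(table.factors))


@dataclass(frozen=True)
class AnovaRow:
    ss: float
    df: int
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    """Per-source decomposition plus the usual fit-quality summaries.

    ``rows`` is keyed by source label (Model, A, ..., D2, Residual,
    Lack of Fit, Pure Error, Cor Total).  When the design has no replicated
    runs, the lack-of-fit and pure-error rows are absent and
    ``pure_error_undefined`` is set.
    """

    rows: dict[str, AnovaRow]
    r2: float
    adj_r2: float
    pred_r2: float | None
    press: float | None
    cv_percent: float
    pure_error_undefined: bool = False

    def to_dict(self) -> dict:
        """JSON-ready mapping with row labels matching the published table."""
        out: dict = {}
        for name, row in self.rows.items():
            entry: dict = {"Sum of squares": row.ss, "df": row.df}
            if row.ms is not None:
                entry["Mean square"] = row.ms
            if row.f is not None:
                entry["F-value"] = row.f
            if row.p is not None:
                entry["p-value"] = row.p
            out[name] = entry
        out["R²"] = self.r2
        out["Adjusted R²"] = self.adj_r2
        if self.pred_r2 is not None:
            out["Predicted R²"] = self.pred_r2
        if self.press is not None:
            out["PRESS"] = self.press
        out["C.V. %"] = self.cv_percent
        return out


def _replicate_groups(table: DesignTable) -> list[np.ndarray]:
    """Positional indices of runs sharing identical factor settings."""
    X = np.round(table.X, 12)
    _, inverse = np.unique(X, axis=0, return_inverse=True)
    return [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]


def anova(model: QuadraticModel, table: DesignTable) -> AnovaTable:
    """Type-III ANOVA of the full quadratic fit on *table*.

    Per-term SS come from reduced-model refits on the coded basis; the
    F statistic for each term is MS(term)/MS(Residual), and the lack-of-fit
    F is MS(LoF)/MS(PureError).  CV% = 100 * sqrt(MS(Residual)) / mean(y).
    """
    y = table.y
    n = len(table)
    names = term_names(table.k)
    n_terms = len(names)
    Z = quadratic_design_matrix(_settings_matrix(table, "coded"))
    _check_rank(Z, names)

    full = sm.OLS(y, Z).fit()
    rss = float(full.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    model_ss = tss - rss
    df_model = n_terms - 1
    df_res = n - n_terms
    ms_res = rss / df_res
    fdist = scipy.stats.f

    rows: dict[str, AnovaRow] = {}
    f_model = (model_ss / df_model) / ms_res
    rows["Model"] = AnovaRow(
        model_ss, df_model, model_ss / df_model, f_model,
        float(fdist.sf(f_model, df_model, df_res)),
    )
    for i, name in enumerate(names[1:], start=1):
        reduced = sm.OLS(y, np.delete(Z, i, axis=1)).fit()
        ss = float(reduced.ssr) - rss
        f_val = ss / ms_res
        rows[name] = AnovaRow(ss, 1, ss, f_val, float(fdist.sf(f_val, 1, df_res)))
    rows["Residual"] = AnovaRow(rss, df_res, ms_res)

    groups = _replicate_groups(table)
    replicated = [g for g in groups if len(g) > 1]
    pure_error_undefined = not replicated
    if pure_error_undefined:
        warnings.warn(
            "design has no replicated runs: pure error and lack of fit are "
            "undefined",
            stacklevel=2,
        )
    else:
        ss_pe = float(sum(np.sum((y[g] - y[g].mean()) ** 2) for g in groups))
        df_pe = n - len(groups)
        ss_lof = rss - ss_pe
        df_lof = len(groups) - n_terms
        ms_pe = ss_pe / df_pe if df_pe > 0 else 0.0
        if ms_pe > 0:
            f_lof = (ss_lof / df_lof) / ms_pe
            p_lof = float(fdist.sf(f_lof, df_lof, df_pe))
        else:  # replicates agree exactly: the F ratio is undefined
            f_lof, p_lof = None, None
        rows["Lack of Fit"] = AnovaRow(
            ss_lof, df_lof, ss_lof / df_lof, f_lof, p_lof,
        )
        rows["Pure Error"] = AnovaRow(ss_pe, df_pe, ss_pe / df_pe if df_pe else None)
    rows["Cor Total"] = AnovaRow(tss, n - 1)

    try:
        press, pred_r2 = press_and_predicted_r2(table)
    except LeverageError:
        press, pred_r2 = None, None
    return AnovaTable(
        rows=rows,
        r2=1.0 - rss / tss,
        adj_r2=1.0 - (rss / df_res) / (tss / (n - 1)),
        pred_r2=pred_r2,
        press=press,
        cv_percent=100.0 * np.sqrt(ms_res) / y.mean(),
        pure_error_undefined=pure_error_undefined,
    )


def press_and_predicted_r2(table: DesignTable) -> tuple[float, float]:
    """Leave-one-out PRESS via the hat-matrix identity e_i / (1 - h_ii).

    The hat matrix depends only on the column space of the basis, so the
    result is identical in coded and actual units.  Raises
    :class:`LeverageError` when any run has leverage 1 (its deletion
    residual, and hence PRESS, is undefined).
    """
    y = table.y
    Z = quadratic_design_matrix(_settings_matrix(table, "coded"))
    _check_rank(Z, term_names(table.k))
    res = sm.OLS(y, Z).fit()
    h = res.get_influence().hat_matrix_diag
    flagged = [table.runs[i].run_id for i in np.flatnonzero(h >= 1.0 - 1e-10)]
    if flagged:
        raise LeverageError(
            f"runs {flagged} have leverage 1; PRESS is undefined"
        )
    press = float(np.sum((res.resid / (1.0 - h)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return press, 1.0 - press / tss


def optimize_surface(
    model: QuadraticModel, bounds: np.ndarray
) -> tuple[np.ndarray, float]:
    """Maximize the fitted quadratic over a box.

    Multi-start projected-gradient search (L-BFGS-B) from all 2^k corners
    plus the center; a quadratic over a box can attain its maximum on the
    boundary, which a single interior start can miss.  Ties within 1e-9 of
    the best value break toward lexicographically smallest settings.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (model.k, 2):
        raise ValueError(f"bounds must have shape ({model.k}, 2)")
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    lo, hi = bounds[:, 0], bounds[:, 1]

    def neg(x: np.ndarray) -> tuple[float, np.ndarray]:
        return -model.predict(x), -model.gradient(x)

    starts = [
        np.where(np.array(mask), hi, lo)
        for mask in itertools.product((False, True), repeat=model.k)
    ]
    starts.append(0.5 * (lo + hi))
    candidates: list[tuple[float, np.ndarray]] = []
    for x0 in starts:
        res = scipy.optimize.minimize(
            neg, x0, jac=True, method="L-BFGS-B",
            bounds=list(zip(lo, hi)), options={"ftol": 1e-12, "gtol": 1e-10},
        )
        candidates.append((-res.fun, res.x))
    best_val = max(v for v, _ in candidates)
    tied = [x for v, x in candidates if v >= best_val - 1e-9]
    best_x = min(tied, key=lambda x: tuple(x))
    return best_x, float(model.predict(best_x))


#: The published actual-unit coefficients of the fitted yield surface, in
#: design-matrix order (intercept, A..D, AB..CD, A^2..D^2).  Kept as literal
#: constants: evaluating the published polynomial is a distinct code path
#: from refitting, because the published rounding shifts predictions by
#: about 0.01.
PUBLISHED_YIELD_COEFFICIENTS = (
    -0.2634,
    0.249903, -0.042711, -0.024221, 0.007521,
    0.001432, -0.000333, -0.00022, 0.000246, -0.000029, -0.000043,
    -0.004767, 0.00023, 0.000179, 4.76e-6,
)


def published_yield_model() -> QuadraticModel:
    """The yield surface exactly as published (actual units, percent yield)."""
    return QuadraticModel.from_coefficients(
        np.array(PUBLISHED_YIELD_COEFFICIENTS), "actual", tuple(paper_factors())
    )
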