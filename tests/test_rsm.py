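import itertools

import numpy as np
import pytest

from pracopt.core_data import DesignRun, DesignTable, FactorSpec
from pracopt.evaluation import r2 as metric_r2
from pracopt.rsm import (
    QuadraticModel,
    SingularDesignError,
    anova,
    fit_quadratic,
    optimize_surface,
    predict,
    press_and_predicted_r2,
    published_yield_model,
    quadratic_design_matrix,
    term_names,
)
from pracopt.synthetic_data import generate_bbd, paper_like_spec, simulate_response


def three_factor_specs():
    return [
        FactorSpec("a", "", -1.0, 0.0, 1.0),
        FactorSpec("b", "", 10.0, 20.0, 30.0),
        FactorSpec("c", "", 0.0, 5.0, 10.0),
    ]


def make_model(k, factors, coefs, units="actual"):
    return QuadraticModel.from_coefficients(np.asarray(coefs, float), units, tuple(factors))


def brute_force_predict(model, x):
    """Independent term-by-term evaluation of the quadratic polynomial."""
    k = model.k
    val = model.intercept
    for i in range(k):
        val += model.linear[i] * x[i]
    for idx, (i, j) in enumerate(itertools.combinations(range(k), 2)):
        val += model.interaction[idx] * x[i] * x[j]
    for i in range(k):
        val += model.quadratic[i] * x[i] ** 2
    return val


class TestPredict:
    def test_matches_brute_force_at_random_points(self, rng):
        factors = three_factor_specs()
        coefs = rng.normal(size=10)
        model = make_model(3, factors, coefs)
        for _ in range(100):
            x = rng.uniform(-2, 2, 3)
            assert predict(model, x) == pytest.approx(
                brute_force_predict(model, x), rel=1e-12
            )

    def test_all_zero_model(self):
        model = make_model(3, three_factor_specs(), np.zeros(10))
        assert predict(model, np.array([3.0, 1.0, -2.0])) == 0.0

    def test_published_polynomial_at_center(self):
        """The published coefficients evaluated at the center point agree
        with the published center prediction of 3.010 (rounding drift < 0.02)."""
        model = published_yield_model()
        value = model.predict(np.array([18.0, 80.0, 90.0, 400.0]))
        assert value == pytest.approx(3.010, abs=0.02)


class TestFitQuadratic:
    def test_exact_recovery_of_noise_free_quadratic(self, rng):
        factors = three_factor_specs()
        true = make_model(3, factors, rng.normal(size=10))
        design = generate_bbd(factors, n_center=3)
        table = design.with_responses(true.predict(design.X))
        fitted = fit_quadratic(table, units="actual")
        np.testing.assert_allclose(
            fitted.coefficients, true.coefficients, atol=1e-8
        )

    def test_fixture_fit_matches_published_equation(self, design):
        model = fit_quadratic(design, units="actual")
        assert model.intercept == pytest.approx(-0.2647, abs=1e-4)
        assert model.linear[0] == pytest.approx(0.249835, abs=1e-6)

    def test_fixture_residual_ss(self, design):
        model = fit_quadratic(design, units="actual")
        resid = design.y - model.predict(design.X)
        assert float(resid @ resid) == pytest.approx(0.8119, abs=5e-4)

    def test_too_few_runs(self, design):
        with pytest.raises(ValueError, match="at least 15 runs"):
            fit_quadratic(design.subset(range(10)))

    def test_collinear_design_raises(self, design):
        # duplicate the time column into the power slot -> C and D collinear
        factors = design.factors[:3] + [FactorSpec("power", "W", 60.0, 90.0, 120.0)]
        runs = [
            DesignRun(r.run_id, r.settings[:3] + (r.settings[2],), r.response)
            for r in design.runs
        ]
        table = DesignTable(factors, runs)
        with pytest.raises(SingularDesignError, match="collinear"):
            fit_quadratic(table)

    def test_unit_conversion_exact_round_trip(self, design):
        model = fit_quadratic(design, units="actual")
        back = model.to_units("coded").to_units("actual")
        np.testing.assert_allclose(
            back.coefficients, model.coefficients, rtol=1e-10, atol=1e-12
        )

    def test_coded_and_actual_fits_are_the_same_surface(self, design):
        ma = fit_quadratic(design, units="actual")
        mc = fit_quadratic(design, units="coded")
        pt_actual = np.array([14.0, 100.0, 90.0, 500.0])
        pt_coded = np.array([-1.0, 1.0, 0.0, 1.0])
        assert ma.predict(pt_actual) == pytest.approx(mc.predict(pt_coded), rel=1e-9)


class TestAnova:
    def test_sum_of_squares_bookkeeping(self, design):
        model = fit_quadratic(design)
        table = anova(model, design)
        rows = table.rows
        assert rows["Cor Total"].df == 28
        assert rows["Model"].ss + rows["Residual"].ss == pytest.approx(
            rows["Cor Total"].ss, rel=1e-8
        )
        assert rows["Lack of Fit"].ss + rows["Pure Error"].ss == pytest.approx(
            rows["Residual"].ss, rel=1e-8
        )
        assert rows["Lack of Fit"].df + rows["Pure Error"].df == rows["Residual"].df

    def test_fixture_summaries(self, design):
        table = anova(fit_quadratic(design), design)
        assert table.rows["Pure Error"].ss == pytest.approx(0.0525, abs=1e-4)
        assert table.rows["Pure Error"].df == 4
        assert table.rows["Model"].f == pytest.approx(7.9, abs=0.05)
        assert table.rows["Model"].p == pytest.approx(0.0002, abs=5e-5)
        assert table.r2 == pytest.approx(0.8876, abs=1e-4)
        assert table.cv_percent == pytest.approx(7.76, abs=0.01)

    def test_per_term_ss_independent_of_model_units(self, design):
        ta = anova(fit_quadratic(design, "actual"), design)
        tc = anova(fit_quadratic(design, "coded"), design)
        for name in term_names(4)[1:]:
            assert ta.rows[name].ss == pytest.approx(tc.rows[name].ss, rel=1e-6)

    def test_r2_consistent_with_metric_module(self, design):
        model = fit_quadratic(design)
        table = anova(model, design)
        assert table.r2 == pytest.approx(
            metric_r2(design.y, model.predict(design.X)), abs=1e-10
        )

    def test_noise_free_data_fits_perfectly(self, rng):
        factors = three_factor_specs()
        true = make_model(3, factors, rng.normal(size=10))
        design = generate_bbd(factors, n_center=3)
        table = design.with_responses(true.predict(design.X))
        result = anova(fit_quadratic(table), table)
        assert result.rows["Residual"].ss == pytest.approx(0.0, abs=1e-12)
        assert result.r2 == pytest.approx(1.0, abs=1e-10)

    def test_no_replicates_flags_pure_error(self, rng):
        factors = three_factor_specs()
        true = make_model(3, factors, rng.normal(size=10))
        design = generate_bbd(factors, n_center=1)
        table = design.with_responses(
            true.predict(design.X) + rng.normal(0, 0.1, len(design))
        )
        with pytest.warns(UserWarning, match="no replicated runs"):
            result = anova(fit_quadratic(table), table)
        assert result.pure_error_undefined
        assert "Lack of Fit" not in result.rows


class TestPress:
    def test_brute_force_leave_one_out(self, rng):
        """PRESS from the hat-matrix identity equals explicit refits with
        each run deleted."""
        factors = three_factor_specs()
        design = generate_bbd(factors, n_center=5)  # 17 runs, 10 terms
        true = make_model(3, factors, rng.normal(size=10))
        table = design.with_responses(
            true.predict(design.X) + rng.normal(0, 0.3, len(design))
        )
        press, pred_r2 = press_and_predicted_r2(table)
        y = table.y
        brute = 0.0
        for i in range(len(table)):
            keep = [j for j in range(len(table)) if j != i]
            sub = table.subset(keep)
            m = fit_quadratic(sub)
            brute += (y[i] - m.predict(table.X[i])) ** 2
        assert press == pytest.approx(brute, rel=1e-8)
        tss = float(np.sum((y - y.mean()) ** 2))
        assert pred_r2 == pytest.approx(1 - brute / tss, rel=1e-8)

    def test_fixture_predicted_r2(self, design):
        press, pred_r2 = press_and_predicted_r2(design)
        assert pred_r2 == pytest.approx(0.3834, abs=5e-4)

    def test_duplicated_noise_free_data(self, rng):
        factors = three_factor_specs()
        true = make_model(3, factors, rng.normal(size=10))
        design = generate_bbd(factors, n_center=3)
        y = true.predict(design.X)
        doubled = DesignTable(
            list(factors),
            [
                DesignRun(i + 1, r.settings, float(v))
                for i, (r, v) in enumerate(
                    list(zip(design.runs, y)) + list(zip(design.runs, y))
                )
            ],
        )
        press, pred_r2 = press_and_predicted_r2(doubled)
        assert press == pytest.approx(0.0, abs=1e-12)
        assert pred_r2 == pytest.approx(1.0, abs=1e-10)


class TestOptimizeSurface:
    def test_one_dimensional_concave(self):
        # y = -(a - 2)^2, flat in the other factors which are pinned at 5.0
        factors = three_factor_specs()
        coefs = np.zeros(10)
        coefs[0] = -4.0  # intercept
        coefs[1] = 4.0  # linear a
        coefs[7] = -1.0  # a^2
        model = make_model(3, factors, coefs)
        bounds = np.array([[0.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        x, val = optimize_surface(model, bounds)
        assert x[0] == pytest.approx(2.0, abs=1e-6)
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_linear_model_ends_at_corner(self):
        factors = three_factor_specs()
        coefs = np.zeros(10)
        coefs[1:4] = [2.0, -1.0, 0.5]
        model = make_model(3, factors, coefs)
        bounds = np.array([[-1.0, 1.0], [10.0, 30.0], [0.0, 10.0]])
        x, _ = optimize_surface(model, bounds)
        np.testing.assert_allclose(x, [1.0, 10.0, 10.0], atol=1e-8)

    def test_fixture_maximum_matches_grid_oracle(self, design):
        model = fit_quadratic(design)
        bounds = np.array([[f.low, f.high] for f in design.factors])
        _, val = optimize_surface(model, bounds)
        axes = [np.linspace(lo, hi, 41) for lo, hi in bounds]
        grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(4, -1).T
        grid_best = model.predict(grid).max()
        assert val >= grid_best - 1e-9
        assert val == pytest.approx(grid_best, abs=1e-3)

    def test_infinite_bounds_rejected(self, design):
        model = fit_quadratic(design)
        bounds = np.array([[14, np.inf], [60, 100], [60, 120], [300, 500]], float)
        with pytest.raises(ValueError, match="finite"):
            optimize_surface(model, bounds)


def test_design_matrix_column_count():
    X = np.zeros((5, 4))
    assert quadratic_design_matrix(X).shape == (5, 15)
    assert len(term_names(4)) == 15
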