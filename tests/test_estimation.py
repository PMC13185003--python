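"""Estimation core: OLS, IRLS logistic, REML mixed model, spline basis."""

import numpy as np
import pytest
from scipy.special import expit

from hbtraj.estimation import (
    ConvergenceError,
    EstimationError,
    SeparationError,
    SingularDesignError,
    SplineBasis,
    fit_lmm,
    fit_logistic,
    fit_ols,
    natural_cubic_basis,
    standardize,
)


class TestOLS:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        y = rng.standard_normal(20)
        fit = fit_ols(X, y)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)  # independent dense solve
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-8)

    def test_exact_linear_data_zero_residuals(self):
        x = np.linspace(0, 10, 15)
        y = 2.0 + 3.0 * x
        fit = fit_ols(np.column_stack([np.ones(15), x]), y)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_intercept_only_gives_mean(self):
        y = np.array([1.0, 4.0, 7.0, 8.0])
        fit = fit_ols(np.ones((4, 1)), y)
        assert fit.coefficients[0] == pytest.approx(y.mean())

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 3))])
        fit = fit_ols(X, rng.standard_normal(50))
        np.testing.assert_allclose(X.T @ fit.residuals, 0.0, atol=1e-8)

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(SingularDesignError):
            fit_ols(X, np.arange(10.0))


class TestLogistic:
    def test_two_by_two_or_equals_cross_product_ratio(self):
        # exposed: 10 events / 10 non-events; unexposed: 5 / 15 -> OR = 3.0
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [10, 10, 5, 15])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [10, 10, 5, 15])
        fit = fit_logistic(np.column_stack([np.ones(40), x]), y,
                           names=["intercept", "exposed"])
        assert np.exp(fit.coef("exposed")) == pytest.approx(3.0, rel=1e-8)

    def test_one_class_response_raises(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(EstimationError, match="one-class"):
            fit_logistic(X, np.zeros(20))

    def test_mle_beats_surrounding_grid(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        y = (rng.random(50) < expit(-0.3 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(50), x])
        fit = fit_logistic(X, y)

        def loglik(b):
            eta = X @ b
            return float(y @ eta - np.logaddexp(0, eta).sum())

        b_hat = fit.coefficients
        grid = np.linspace(-1.0, 1.0, 9)
        for d0 in grid:
            for d1 in grid:
                assert fit.loglik >= loglik(b_hat + [d0, d1]) - 1e-9

    def test_score_at_mle_is_zero(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        y = (rng.random(200) < expit(X @ [0.2, -0.5, 0.9])).astype(float)
        fit = fit_logistic(X, y)
        score = X.T @ (y - expit(X @ fit.coefficients))
        assert np.abs(score).max() < 1e-6

    def test_complete_separation_detected_with_column_name(self):
        x = np.concatenate([np.linspace(-3, -1, 20), np.linspace(1, 3, 20)])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError, match="sep_col"):
            fit_logistic(np.column_stack([np.ones(40), x]), y,
                         names=["intercept", "sep_col"])

    def test_or_table_ci_straddles_point(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(300)
        y = (rng.random(300) < expit(0.5 * x)).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(300), x]), y,
                           names=["intercept", "x"],
                           scales={"x": (5.0, "per 5 units")})
        tab = fit.or_table().set_index("term")
        assert tab.loc["x", "or_lo"] < tab.loc["x", "or"] < tab.loc["x", "or_hi"]
        # scaled OR is exp(5 * beta)
        assert tab.loc["x", "or"] == pytest.approx(np.exp(5 * fit.coef("x")))


def _balanced_random_intercept_data(m=40, n=4, mu=10.0, sb=2.0, se=1.0, seed=0):
    rng = np.random.default_rng(seed)
    b = rng.normal(0, sb, m)
    y = mu + np.repeat(b, n) + rng.normal(0, se, m * n)
    groups = np.repeat(np.arange(m), n)
    X = np.ones((m * n, 1))
    return X, y, groups, m, n


class TestLMM:
    def test_balanced_matches_closed_form_anova_reml(self):
        X, y, groups, m, n = _balanced_random_intercept_data(seed=11)
        fit = fit_lmm(X, X, y, groups, n_starts=2)
        # closed-form balanced one-way REML (= ANOVA) estimators
        ybar_i = y.reshape(m, n).mean(axis=1)
        ybar = y.mean()
        msw = ((y.reshape(m, n) - ybar_i[:, None]) ** 2).sum() / (m * (n - 1))
        msb = n * ((ybar_i - ybar) ** 2).sum() / (m - 1)
        sb2 = (msb - msw) / n
        assert fit.sigma2 == pytest.approx(msw, abs=1e-6)
        assert fit.re_cov[0, 0] == pytest.approx(sb2, abs=1e-6)
        assert fit.fixed_effects[0] == pytest.approx(ybar, abs=1e-8)

    def test_zero_variance_truth_shrinks_blups(self):
        rng = np.random.default_rng(12)
        m, n = 60, 3
        groups = np.repeat(np.arange(m), n)
        X = np.ones((m * n, 1))
        y = 5.0 + rng.normal(0, 1.0, m * n)  # no subject effect at all
        fit = fit_lmm(X, X, y, groups, n_starts=2)
        assert fit.re_cov[0, 0] < 0.15
        assert np.abs(fit.blups.to_numpy()).max() < 0.8
        assert fit.boundary or fit.re_cov[0, 0] >= 0

    def test_matches_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        import pandas as pd

        rng = np.random.default_rng(13)
        m, n = 80, 3
        groups = np.repeat(np.arange(m), n)
        t = np.tile(np.array([0.0, 1.0, 2.0]), m)
        b0 = rng.normal(0, 2.0, m)
        b1 = rng.normal(0, 0.8, m)
        y = 1.0 + 0.5 * t + b0[groups] + b1[groups] * t + rng.normal(0, 1.0, m * n)
        X = np.column_stack([np.ones(m * n), t])
        fit = fit_lmm(X, X, y, groups, n_starts=3)
        df = pd.DataFrame({"y": y, "t": t, "g": groups})
        ref = sm.MixedLM.from_formula(
            "y ~ t", groups="g", re_formula="~t", data=df
        ).fit(reml=True)
        np.testing.assert_allclose(fit.fixed_effects, ref.fe_params.values, atol=1e-4)
        np.testing.assert_allclose(fit.re_cov, ref.cov_re.values, atol=0.05)
        assert fit.sigma2 == pytest.approx(ref.scale, abs=0.05)

    def test_reml_optimum_beats_random_perturbations(self):
        X, y, groups, m, n = _balanced_random_intercept_data(seed=14)
        fit = fit_lmm(X, X, y, groups, n_starts=2)

        def neg2_reml(sb2, se2):
            # direct REML criterion for the one-way balanced model
            ybar_i = y.reshape(m, n).mean(axis=1)
            V_diag = se2 + n * sb2
            ll = 0.0
            # within-subject contrasts
            rw = (y.reshape(m, n) - ybar_i[:, None]).ravel()
            ll += m * (n - 1) * np.log(se2) + (rw @ rw) / se2
            # between-subject part with REML correction
            r = ybar_i - y.mean()
            ll += m * np.log(V_diag / n) + n * (r @ r) / V_diag
            ll += np.log(m * n / V_diag * n / n)  # log|X'V^-1X| up to constant
            return ll

        best = neg2_reml(max(fit.re_cov[0, 0], 1e-8), fit.sigma2)
        rng = np.random.default_rng(15)
        for _ in range(50):
            sb2 = fit.re_cov[0, 0] * np.exp(rng.uniform(-1, 1)) + 1e-6
            se2 = fit.sigma2 * np.exp(rng.uniform(-1, 1))
            assert best <= neg2_reml(sb2, se2) + 1e-4

    def test_blup_sample_mean_near_zero(self, three_visit_cohort):
        from hbtraj.two_stage import fit_stage1

        three, _ = three_visit_cohort
        fit = fit_stage1(three, seed=0)
        means = fit.blups.mean()
        sds = fit.blups.std()
        assert (means.abs() < 0.15 * sds + 1e-8).all()


class TestSplineBasis:
    def test_linear_beyond_boundary_knots(self):
        basis = SplineBasis([5.0, 10.0, 15.0], (0.0, 20.0))
        x = np.concatenate([np.linspace(-10, -1, 30), np.linspace(21, 40, 30)])
        B = basis.evaluate(x)
        # second differences vanish where the basis must be linear
        h = np.diff(x)
        for j in range(B.shape[1]):
            d2 = np.diff(np.diff(B[:30, j]) / h[:29])
            np.testing.assert_allclose(d2, 0.0, atol=1e-8)
            d2 = np.diff(np.diff(B[30:, j]) / np.diff(x[30:]))
            np.testing.assert_allclose(d2, 0.0, atol=1e-8)

    def test_zero_interior_knots_is_affine(self):
        basis, B = natural_cubic_basis(np.linspace(0, 10, 20), [], (0.0, 10.0))
        assert basis.dim == 1
        np.testing.assert_allclose(B[:, 0], np.linspace(0, 10, 20))

    def test_dimension_rule(self):
        for m in range(4):
            knots = np.linspace(2, 8, m + 2)[1:-1] if m else []
            basis = SplineBasis(knots, (0.0, 10.0))
            assert basis.dim == m + 1

    def test_span_round_trip_projection(self):
        rng = np.random.default_rng(16)
        basis = SplineBasis([3.0, 6.0], (0.0, 10.0))
        x = np.linspace(0, 10, 60)
        B = np.column_stack([np.ones(60), basis.evaluate(x)])
        f = B @ rng.standard_normal(B.shape[1])  # any function in the span
        coef, *_ = np.linalg.lstsq(B, f, rcond=None)
        np.testing.assert_allclose(B @ coef, f, atol=1e-8)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(EstimationError, match="increasing"):
            SplineBasis([5.0, 5.0], (0.0, 10.0))

    def test_penalty_annihilates_linear_functions(self):
        basis = SplineBasis([4.0, 8.0], (0.0, 12.0))
        S = basis.penalty()
        # the coefficient vector reproducing f(x)=x is (1, 0, ..., 0)
        e1 = np.zeros(basis.dim)
        e1[0] = 1.0
        assert abs(e1 @ S @ e1) < 1e-6
        assert np.linalg.eigvalsh(S).min() > -1e-8


class TestStandardize:
    def test_basic_moments(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0])
        assert mean == 2.0 and sd == 1.0
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(17)
        v = rng.normal(10, 3, 100)
        z1, *_ = standardize(v)
        z2, m, s = standardize(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)
        assert abs(m) < 1e-12 and s == pytest.approx(1.0)

    def test_round_trip(self):
        rng = np.random.default_rng(18)
        v = rng.normal(5, 2, 50)
        z, m, s = standardize(v)
        np.testing.assert_allclose(z * s + m, v, atol=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(EstimationError, match="constant"):
            standardize([2.0, 2.0, 2.0])
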