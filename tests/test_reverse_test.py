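"""Reverse-test internals: OLS, Wald, ROR, set test, transform, diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from gxereverse import (
    CollinearityError,
    DegenerateVarianceError,
    DesignMatrix,
    DesignSpec,
    GxEDataset,
    build_design,
    diagnostics,
    estimate_ror,
    fit_ols,
    set_test,
    wald_gd,
    yeo_johnson,
)


def make_design(X, gd_index=None):
    return DesignMatrix(
        values=np.asarray(X, float),
        column_map={f"c{i}": i for i in range(np.asarray(X).shape[1])},
        gd_index=gd_index,
    )


def normal_equations_oracle(X, y):
    """Brute-force (X'X)^-1 X'y, independent of the fit path."""
    xtx_inv = np.linalg.inv(X.T @ X)
    return xtx_inv @ (X.T @ y), xtx_inv


class TestFitOLS:
    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 4))])
        y = rng.standard_normal(50)
        fit = fit_ols(make_design(X), y)
        coef_oracle, xtx_inv = normal_equations_oracle(X, y)
        np.testing.assert_allclose(fit.coef, coef_oracle, atol=1e-10)
        resid = y - X @ coef_oracle
        sigma2 = resid @ resid / (50 - 5)
        np.testing.assert_allclose(fit.sigma2_hat, sigma2, rtol=1e-10)
        np.testing.assert_allclose(fit.cov_model, sigma2 * xtx_inv, rtol=1e-8)

    def test_exact_fit_has_zero_residuals(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = 2.0 - 3.0 * X[:, 1]
        fit = fit_ols(make_design(X), y)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)
        assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-24)

    def test_intercept_only(self, rng):
        y = rng.standard_normal(30)
        fit = fit_ols(make_design(np.ones((30, 1))), y)
        assert fit.coef[0] == pytest.approx(y.mean())
        assert fit.sigma2_hat == pytest.approx(y.var(ddof=1))

    def test_collinear_design_rejected(self, rng):
        z = rng.standard_normal(40)
        X = np.column_stack([np.ones(40), z, 2.0 * z])
        with pytest.raises(CollinearityError):
            fit_ols(make_design(X), rng.standard_normal(40))

    def test_covariances_symmetric_psd(self, rng):
        X = np.column_stack([np.ones(100), rng.standard_normal((100, 3))])
        fit = fit_ols(make_design(X), rng.standard_normal(100))
        for cov in (fit.cov_model, fit.cov_sandwich):
            np.testing.assert_allclose(cov, cov.T, atol=1e-14)
            assert np.linalg.eigvalsh(cov).min() > -1e-12


class TestWaldGD:
    def test_equals_squared_t_statistic(self, random_dataset, spline_design_spec):
        dm = build_design(random_dataset, spline_design_spec, "reverse")
        fit = fit_ols(dm, random_dataset.x)
        res = wald_gd(fit, dm, variance="model")
        sm_fit = sm.OLS(random_dataset.x, dm.values).fit()
        assert res.stat == pytest.approx(sm_fit.tvalues[dm.gd_index] ** 2, rel=1e-10)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(res.stat, 1))

    def test_sandwich_matches_statsmodels_hc0(self, random_dataset, spline_design_spec):
        dm = build_design(random_dataset, spline_design_spec, "reverse")
        fit = fit_ols(dm, random_dataset.x)
        sm_fit = sm.OLS(random_dataset.x, dm.values).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.cov_sandwich, sm_fit.cov_params(), rtol=1e-8)

    def test_zero_coefficient_gives_unit_p(self):
        # orthogonal balanced layout with y symmetric: exact zero GD estimate
        g = np.array([0.0, 0, 1, 1, 0, 0, 1, 1])
        d = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
        X = np.column_stack([np.ones(8), g, d, g * d])
        y = np.array([0.0, 1, 0, 1, 2, 3, 2, 3])  # same D-shift in both G groups
        fit = fit_ols(make_design(X, gd_index=3), y)
        res = wald_gd(fit, make_design(X, gd_index=3), variance="model")
        assert fit.coef[3] == pytest.approx(0.0, abs=1e-12)
        assert res.stat == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_affine_invariance_of_statistic(self, random_dataset, spline_design_spec):
        """tau^2 is unchanged by y -> a*y + b (a != 0)."""
        dm = build_design(random_dataset, spline_design_spec, "reverse")
        base = wald_gd(fit_ols(dm, random_dataset.x), dm)
        moved = wald_gd(fit_ols(dm, -2.5 * random_dataset.x + 7.0), dm)
        assert moved.stat == pytest.approx(base.stat, rel=1e-9)

    def test_degenerate_variance_raises(self):
        X = np.column_stack([np.ones(4), [0.0, 0, 1, 1], [0.0, 1, 0, 1], [0.0, 0, 0, 1]])
        dm = make_design(X, gd_index=3)
        fit = fit_ols(dm, X @ [1.0, 2.0, 3.0, 4.0])  # saturated: zero residual variance
        with pytest.raises(DegenerateVarianceError):
            wald_gd(fit, dm)

    def test_sandwich_controls_size_under_heteroskedasticity(self):
        """Var(eps) proportional to 1+G with an unbalanced G (a balanced
        two-group split makes the model variance accidentally correct for
        the GD contrast): model-based Wald is anticonservative, the
        sandwich Wald keeps its 5% size (10,000 null replicates)."""
        root = np.random.SeedSequence(513)
        n, reps = 4000, 10_000
        rej_model = rej_sand = 0
        for child in root.spawn(reps):
            r = np.random.default_rng(child)
            g = (r.random(n) < 0.15).astype(float)
            d = (r.random(n) < 0.5).astype(float)
            X = np.column_stack([np.ones(n), g, d, g * d])
            y = 0.5 * g + 0.5 * d + np.sqrt(1.0 + g) * r.standard_normal(n)
            dm = make_design(X, gd_index=3)
            fit = fit_ols(dm, y)
            rej_model += wald_gd(fit, dm, variance="model").p_value < 0.05
            rej_sand += wald_gd(fit, dm, variance="sandwich").p_value < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej_sand / reps - 0.05) < band + 0.002  # HC0 finite-sample slack
        assert rej_model / reps > 0.05 + band


class TestROR:
    def test_null_coefficient_gives_unit_ror(self):
        g = np.array([0.0, 0, 1, 1, 0, 0, 1, 1])
        d = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
        X = np.column_stack([np.ones(8), g, d, g * d])
        y = np.array([0.0, 1, 0, 1, 2, 3, 2, 3]) + np.array([0.1, -0.1] * 4)
        fit = fit_ols(make_design(X, gd_index=3), y)
        res = estimate_ror(fit)
        assert res.dmd_hat == pytest.approx(fit.coef[3])
        assert res.ror_hat == pytest.approx(np.exp(fit.coef[3] / fit.sigma2_hat))
        assert res.ci_lower < res.ror_hat < res.ci_upper

    def test_forced_value(self):
        """bgd = ln 1.5 with sigma2 = 1 must give ROR = 1.5 exactly."""
        fit_like = fit_ols(make_design(np.ones((10, 1)), gd_index=None), np.zeros(10))
        fit_like.coef = np.array([np.log(1.5)])
        fit_like.sigma2_hat = 1.0
        fit_like.cov_model = np.array([[0.01]])
        fit_like.gd_index = 0
        fit_like.df_resid = 9
        assert estimate_ror(fit_like).ror_hat == pytest.approx(1.5)

    def test_ci_coverage_under_compatible_model(self):
        """95% CI covers the generating ROR at the nominal rate (n = 2000)."""
        from gxereverse.evaluation import _simulate_case_control_fast, default_design_spec
        from gxereverse.simulator import ScenarioSpec, resolve_params

        spec = ScenarioSpec(p0=0.05, or_x=1.5, ror=1.5, genotype_coding="ordinal")
        params = resolve_params(spec)
        dspec = default_design_spec()
        covered = 0
        reps = 500
        for child in np.random.SeedSequence(77).spawn(reps):
            r = np.random.default_rng(child)
            cc = _simulate_case_control_fast(spec, params, r)
            dm = build_design(cc, dspec, "reverse")
            res = estimate_ror(fit_ols(dm, cc.x))
            covered += res.ci_lower <= spec.ror <= res.ci_upper
        band = 1.96 * np.sqrt(0.95 * 0.05 / reps)
        assert abs(covered / reps - 0.95) < band + 0.01


class TestSetTest:
    def _multi_marker_fit(self, r, n=600, effects=(0.0, 0.0, 0.0)):
        d = (r.random(n) < 0.5).astype(float)
        G = (r.random((n, 3)) < 0.3).astype(float)
        X = np.column_stack([np.ones(n), G, d, G * d[:, None]])
        y = G @ [0.1, 0.1, 0.1] + 0.3 * d + (G * d[:, None]) @ list(effects) + r.standard_normal(n)
        dm = make_design(X, gd_index=None)
        return fit_ols(dm, y), dm

    def test_single_index_reduces_to_wald_gd(self, random_dataset, spline_design_spec):
        dm = build_design(random_dataset, spline_design_spec, "reverse")
        fit = fit_ols(dm, random_dataset.x)
        single = set_test(fit, dm, [dm.gd_index])
        ref = wald_gd(fit, dm)
        assert single.stat == pytest.approx(ref.stat, rel=1e-12)
        assert single.df == 1

    def test_null_size_chi2_3(self):
        reps, rej = 2000, 0
        for child in np.random.SeedSequence(901).spawn(reps):
            r = np.random.default_rng(child)
            fit, dm = self._multi_marker_fit(r)
            rej += set_test(fit, dm, [5, 6, 7]).p_value < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < band + 0.005

    def test_power_exceeds_null_rate(self):
        reps = 300
        rej_null = rej_alt = 0
        for child in np.random.SeedSequence(902).spawn(reps):
            r = np.random.default_rng(child)
            fit, dm = self._multi_marker_fit(r)
            rej_null += set_test(fit, dm, [5, 6, 7]).p_value < 0.05
            fit_a, dm_a = self._multi_marker_fit(r, effects=(0.6, 0.0, 0.0))
            rej_alt += set_test(fit_a, dm_a, [5, 6, 7]).p_value < 0.05
        assert rej_alt > rej_null


class TestYeoJohnson:
    def test_gamma_one_is_identity(self, rng):
        x = rng.uniform(0, 10, 50)
        out, g = yeo_johnson(x, gamma=1.0)
        np.testing.assert_allclose(out, x)
        assert g == 1.0

    def test_zero_maps_to_zero_for_any_gamma(self):
        for gamma in (-1.5, -0.074, 0.0, 0.5, 2.0):
            out, _ = yeo_johnson(np.array([0.0]), gamma=gamma)
            assert out[0] == pytest.approx(0.0)

    def test_gamma_zero_limit_is_log1p(self, rng):
        x = rng.uniform(0, 20, 100)
        exact, _ = yeo_johnson(x, gamma=0.0)
        near, _ = yeo_johnson(x, gamma=1e-6)
        np.testing.assert_allclose(exact, np.log1p(x))
        np.testing.assert_allclose(near, np.log1p(x), rtol=1e-4)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            yeo_johnson(np.array([-0.5, 1.0]))

    def test_estimate_recovers_log_scale(self, rng):
        # data generated as expm1(normal): log1p(x) is normal, so gamma ~ 0
        x = np.expm1(np.clip(rng.normal(2.0, 0.5, 5000), 0.0, None))
        _, gamma = yeo_johnson(x, "estimate")
        assert abs(gamma) < 0.1


class TestDiagnostics:
    def _fit(self, r, n, noise):
        g = (r.random(n) < 0.3).astype(float)
        d = (r.random(n) < 0.5).astype(float)
        X = np.column_stack([np.ones(n), g, d, g * d])
        y = 0.2 * g + 0.4 * d + noise
        dm = make_design(X, gd_index=3)
        return fit_ols(dm, y), dm

    def test_normality_p_uniform_under_gaussian_errors(self):
        reps, n = 400, 500
        pvals = []
        for child in np.random.SeedSequence(333).spawn(reps):
            r = np.random.default_rng(child)
            fit, dm = self._fit(r, n, r.standard_normal(n))
            pvals.append(diagnostics(fit, dm).normality_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_normality_power_on_rectified_errors(self):
        from gxereverse.simulator import _rectified_standard_noise

        reps, n, rej = 100, 2000, 0
        for child in np.random.SeedSequence(334).spawn(reps):
            r = np.random.default_rng(child)
            fit, dm = self._fit(r, n, _rectified_standard_noise(n, r))
            rej += diagnostics(fit, dm).normality_p < 0.05
        assert rej / reps > 0.9

    def test_white_test_near_nominal_when_homoskedastic(self):
        # continuous covariates so the White auxiliary regression is full rank
        reps, n, rej = 400, 500, 0
        for child in np.random.SeedSequence(335).spawn(reps):
            r = np.random.default_rng(child)
            X = np.column_stack([np.ones(n), r.standard_normal(n), r.standard_normal(n)])
            dm = make_design(X)
            fit = fit_ols(dm, 0.3 * X[:, 1] + r.standard_normal(n))
            rej += diagnostics(fit, dm).heteroskedasticity_p < 0.05
        band = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < band + 0.015

    def test_small_sample_rejected(self, rng):
        X = np.column_stack([np.ones(8), rng.standard_normal((8, 3))])
        fit = fit_ols(make_design(X), rng.standard_normal(8))
        with pytest.raises(Exception, match="[Ss]mall|n="):
            diagnostics(fit, make_design(X))
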