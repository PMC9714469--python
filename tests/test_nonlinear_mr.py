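import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from curvemr import (
    curve_with_significance, fp_derivative_basis, fp_meta_regression,
    fp_test, iv_free_exposure, lace_estimates, nonlinear_mr_fit, select_fp,
    stratify_by_residual, trend_test,
)
from curvemr.nonlinear_mr import (
    FpModel, _wls_known_variance, fp_antiderivative_basis, linear_model,
)


def _strata_from_slope(slope_fn, x=None, se=0.05):
    x = np.asarray(x if x is not None else np.linspace(2.0, 4.6, 10))
    return pd.DataFrame({
        "stratum": np.arange(len(x)), "n": 400,
        "mean_exposure": x, "lace": slope_fn(x), "se": se,
    })


class TestIvFreeExposure:
    def test_orthogonal_to_grs_and_constant(self, rng):
        z = rng.normal(size=500)
        x = 3.0 + 0.4 * z + rng.normal(0, 0.5, 500)
        r = iv_free_exposure(x, z)
        assert abs(np.mean(r)) < 1e-10
        assert abs(np.corrcoef(r, z)[0, 1]) < 1e-10

    def test_four_point_oracle(self):
        # x = 2z exactly: residuals are identically zero
        z = np.array([0.0, 1.0, 2.0, 3.0])
        r = iv_free_exposure(2.0 * z, z)
        assert np.allclose(r, 0.0, atol=1e-12)
        # hand-computed residual for a non-degenerate case
        x = np.array([1.0, 2.0, 2.0, 5.0])
        slope = np.polyfit(z, x, 1)[0]
        expect = x - x.mean() - slope * (z - z.mean())
        assert np.allclose(iv_free_exposure(x, z), expect, atol=1e-12)

    def test_constant_grs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            iv_free_exposure([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestStratify:
    def test_sizes_differ_by_at_most_one(self, rng):
        a = stratify_by_residual(rng.normal(size=103), 10)
        counts = np.bincount(a, minlength=10)
        assert counts.min() == 10 and counts.max() == 11
        assert counts.sum() == 103

    def test_ordering_respects_residual_ranks(self, rng):
        r = rng.normal(size=200)
        a = stratify_by_residual(r, 10)
        for k in range(9):
            assert r[a == k].max() <= r[a == k + 1].min() + 1e-12

    def test_too_small_sample_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            stratify_by_residual(rng.normal(size=99), 10)
        with pytest.raises(ValueError, match="strata"):
            stratify_by_residual(rng.normal(size=100), 1)

    def test_all_ties_warns_but_partitions(self):
        with pytest.warns(UserWarning, match="identical"):
            a = stratify_by_residual(np.zeros(40), 2)
        assert np.bincount(a).tolist() == [20, 20]


class TestFpBases:
    def test_hand_computed_values(self):
        x = np.array([2.0, 3.0])
        assert np.allclose(fp_derivative_basis(x, (1.0,))[:, 0], [1.0, 1.0])
        assert np.allclose(fp_derivative_basis(x, (2.0,))[:, 0], [4.0, 6.0])
        assert np.allclose(fp_derivative_basis(x, (0.0,))[:, 0], [0.5, 1 / 3])
        got = fp_derivative_basis(np.array([2.0]), (2.0, 2.0))
        assert got[0, 1] == pytest.approx(2.0 * (2.0 * np.log(2.0) + 1.0))
        got0 = fp_derivative_basis(np.array([2.0]), (0.0, 0.0))
        assert got0[0, 1] == pytest.approx(2.0 * np.log(2.0) / 2.0)

    @pytest.mark.parametrize("powers", [
        (1.0,), (0.0,), (-2.0,), (0.5,), (2.0, 3.0), (2.0, 2.0),
        (0.0, 0.0), (0.0, 1.0), (-1.0, -1.0),
    ])
    def test_derivative_matches_numeric_gradient_of_antiderivative(self, powers):
        x = np.linspace(1.5, 5.0, 4001)
        A = fp_antiderivative_basis(x, powers)
        D = fp_derivative_basis(x, powers)
        for j in range(A.shape[1]):
            num = np.gradient(A[:, j], x)
            assert np.allclose(num[5:-5], D[5:-5, j], rtol=1e-4, atol=1e-6)

    def test_nonpositive_x_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fp_derivative_basis([-1.0], (1.0,))
        with pytest.raises(ValueError, match="positive"):
            fp_antiderivative_basis([0.0], (1.0,))


class TestWls:
    def test_constant_lace_recovered_exactly(self):
        # h'(x) = c is the power-1 derivative model with coefficient c
        strata = _strata_from_slope(lambda x: np.full_like(x, -0.4))
        m = fp_meta_regression(strata, 1)
        assert m.powers == (1.0,)
        assert m.coefficients[0] == pytest.approx(-0.4)

    def test_se_scaling_of_coefficient_variance(self):
        strata = _strata_from_slope(lambda x: 0.2 * x, se=0.05)
        inflated = strata.assign(se=0.10)
        a = fp_meta_regression(strata, 1)
        b = fp_meta_regression(inflated, 1)
        assert b.cov[0, 0] == pytest.approx(4.0 * a.cov[0, 0], rel=1e-10)
        assert b.coefficients[0] == pytest.approx(a.coefficients[0], rel=1e-10)

    def test_matches_closed_form_single_regressor(self, rng):
        y = rng.normal(size=8)
        X = rng.normal(size=(8, 1))
        se = rng.uniform(0.5, 2.0, 8)
        beta, cov, _ = _wls_known_variance(y, X, se)
        w = 1 / se**2
        expect = np.sum(w * X[:, 0] * y) / np.sum(w * X[:, 0] ** 2)
        assert beta[0] == pytest.approx(expect, rel=1e-12)
        assert cov[0, 0] == pytest.approx(1 / np.sum(w * X[:, 0] ** 2), rel=1e-12)


class TestFpSelection:
    def test_quadratic_truth_recovers_power_two(self):
        # h(x) = x^2 -> h'(x) = 2x, the power-2 derivative term with coef 1
        strata = _strata_from_slope(lambda x: 2.0 * x, se=0.02)
        m = fp_meta_regression(strata, 1)
        assert m.powers == (2.0,)
        assert m.coefficients[0] == pytest.approx(1.0, abs=1e-8)

    def test_degree_two_not_adopted_without_evidence(self):
        strata = _strata_from_slope(lambda x: np.full_like(x, 0.3), se=0.05)
        best = select_fp(strata, degree_max=2)
        assert best.degree == 1

    def test_degree_two_adopted_for_genuine_mixture(self, rng):
        # slope 1/x + x (antiderivative ln x + x^2/2) with tiny noise
        x = np.linspace(1.2, 6.0, 12)
        lace = 1.0 / x + x + rng.normal(0, 0.005, 12)
        strata = pd.DataFrame({"stratum": range(12), "n": 400,
                               "mean_exposure": x, "lace": lace, "se": 0.005})
        best = select_fp(strata, degree_max=2)
        assert best.degree == 2

    def test_too_few_strata_rejected(self):
        strata = _strata_from_slope(lambda x: x, x=np.array([2.0, 3.0]))
        with pytest.raises(ValueError, match="strata"):
            fp_meta_regression(strata, 1)


class TestTrendAndFpTests:
    def test_constant_lace_trend_p_near_one(self):
        strata = _strata_from_slope(lambda x: np.full_like(x, -0.3))
        assert trend_test(strata) > 0.999

    def test_strong_trend_detected(self):
        strata = _strata_from_slope(lambda x: 0.5 * x, se=0.01)
        assert trend_test(strata) < 1e-10

    def test_fp_test_is_one_when_linear_wins(self):
        strata = _strata_from_slope(lambda x: np.full_like(x, 0.2), se=0.05)
        best = select_fp(strata, degree_max=2)
        lin = linear_model(strata)
        if best.powers == (1.0,):
            assert fp_test(best, lin) == 1.0

    def test_fp_test_chi_square_definition(self):
        strata = _strata_from_slope(lambda x: 2.0 * x, se=0.02)
        best = fp_meta_regression(strata, 1)  # power 2
        lin = linear_model(strata)
        stat = 2.0 * (best.loglik - lin.loglik)
        assert fp_test(best, lin) == pytest.approx(float(sps.chi2.sf(stat, 1)))

    def test_trend_equals_fp_powers_one_two(self):
        # The intercept-plus-slope trend regression spans the same space as
        # the degree-2 FP derivative with powers (1, 2): h' = b1 + 2 b2 x.
        # The slope z-statistic (and p) must therefore agree exactly.
        rng = np.random.default_rng(3)
        x = np.linspace(2.0, 4.6, 10)
        lace = 0.1 - 0.25 * x + rng.normal(0, 0.03, 10)
        strata = pd.DataFrame({"stratum": range(10), "n": 400,
                               "mean_exposure": x, "lace": lace,
                               "se": rng.uniform(0.03, 0.08, 10)})
        y, se = strata["lace"].to_numpy(), strata["se"].to_numpy()
        B = fp_derivative_basis(x, (1.0, 2.0))
        beta, cov, _ = _wls_known_variance(y, B, se)
        z_fp = beta[1] / np.sqrt(cov[1, 1])
        p_fp = 2 * sps.norm.sf(abs(z_fp))
        assert trend_test(strata) == pytest.approx(p_fp, rel=1e-10)

    def test_too_few_strata(self):
        strata = _strata_from_slope(lambda x: x, x=np.array([2.0, 3.0]))
        with pytest.raises(ValueError):
            trend_test(strata)


class TestCurveSignificance:
    def _model(self, powers, coef, cov_scale, x=None):
        x = x if x is not None else np.linspace(2.0, 4.6, 10)
        k = len(powers)
        return FpModel(degree=len(powers), powers=powers,
                       coefficients=np.asarray(coef, float),
                       cov=cov_scale * np.eye(k), loglik=0.0,
                       mean_exposures=np.asarray(x))

    def test_tight_monotone_curve_all_significant(self):
        m = self._model((1.0,), [-0.4], 1e-8)
        curve = curve_with_significance(m, np.linspace(2.0, 4.6, 40))
        assert curve["significant"].all()
        assert (np.diff(curve["effect"]) < 0).all()

    def test_huge_uncertainty_nothing_significant(self):
        m = self._model((1.0,), [-0.4], 25.0)
        curve = curve_with_significance(m, np.linspace(2.0, 4.6, 40))
        assert not curve["significant"].any()

    def test_reference_point_is_zero_effect(self):
        m = self._model((2.0,), [0.3], 1e-4)
        # step 0.1 so x = 3.0 lies exactly on the grid
        curve = curve_with_significance(m, np.linspace(2.0, 4.6, 27), reference=3.0)
        i = int(np.argmin(np.abs(curve["x"] - 3.0)))
        assert abs(curve["effect"].iloc[i]) < 1e-6
        assert curve.attrs["reference_x"] == 3.0

    def test_u_shape_insignificant_near_vertex(self):
        # h'(x) = x - 3.2 (powers (1, 2), coefficients chosen accordingly)
        m = self._model((1.0, 2.0), [-3.2, 0.5], 1e-4)
        grid = np.linspace(2.0, 4.6, 53)
        curve = curve_with_significance(m, grid, reference=3.2)
        near = curve[np.abs(curve.x - 3.2) < 0.05]
        assert not near["significant"].any()
        assert curve[curve.x < 2.4]["significant"].all()
        assert curve[curve.x > 4.2]["significant"].all()

    def test_extrapolation_warns(self):
        m = self._model((1.0,), [0.2], 1e-4)
        with pytest.warns(UserWarning, match="extrapolation"):
            curve_with_significance(m, np.linspace(1.0, 6.0, 30))

    def test_nonpositive_grid_rejected(self):
        m = self._model((1.0,), [0.2], 1e-4)
        with pytest.raises(ValueError, match="positive"):
            curve_with_significance(m, np.array([-1.0, 2.0]))


class TestEndToEnd:
    def test_linear_protective_laces_homogeneous(self, linear_protective_cohort):
        sim = linear_protective_cohort
        fit = nonlinear_mr_fit(sim.table, sim.grs, "diabetes", "logistic",
                               n_strata=5)
        s = fit.strata
        # Cochran Q against the IVW mean: no evidence of heterogeneity
        w = 1 / s["se"] ** 2
        mu = np.sum(w * s["lace"]) / np.sum(w)
        q = float(np.sum(w * (s["lace"] - mu) ** 2))
        assert sps.chi2.sf(q, len(s) - 1) > 0.01
        assert fit.trend_p > 0.001  # no spurious nonlinearity signal

    def test_causal_u_lace_rises_with_exposure(self):
        from curvemr import preset, simulate_cohort

        sim = simulate_cohort(preset("CAUSAL_U", n_individuals=20_000, seed=2))
        fit = nonlinear_mr_fit(sim.table, sim.grs, "diabetes", "logistic",
                               n_strata=10)
        rho = sps.spearmanr(fit.strata["mean_exposure"], fit.strata["lace"]).statistic
        assert rho > 0.5
        assert fit.trend_p < 0.05

    def test_stratum_relabeling_invariance(self, spurious_u_cohort):
        sim = spurious_u_cohort
        t = sim.table
        resid = iv_free_exposure(t["ldl_c"].to_numpy(), sim.grs)
        strata = stratify_by_residual(resid, 5)
        a = lace_estimates(t, sim.grs, "diabetes", "logistic", strata)
        b = lace_estimates(t, sim.grs, "diabetes", "logistic", 10 - strata)
        assert np.allclose(a["lace"], b["lace"])
        assert np.allclose(a["mean_exposure"], b["mean_exposure"])

    def test_constant_slope_recovered_from_laces(self, linear_protective_cohort):
        sim = linear_protective_cohort
        fit = nonlinear_mr_fit(sim.table, sim.grs, "fbg", "linear", n_strata=5)
        # IVW mean of the LACEs approximates the preset's linear fbg effect
        s = fit.strata
        w = 1 / s["se"] ** 2
        mu = float(np.sum(w * s["lace"]) / np.sum(w))
        pooled_se = float(np.sqrt(1 / np.sum(w)))
        assert mu == pytest.approx(-0.14, abs=4 * pooled_se)
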