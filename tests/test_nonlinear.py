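"""Non-linear MR: IV-free residuals, stratification, LACE, tests and curves."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from telomr.genetics import build_grs
from telomr.nonlinear import (FRACPOLY_POWERS, StratumResult, _fracpoly_antiderivative,
                              cochran_q_test, fracpoly_curve, fracpoly_test,
                              iv_free_exposure, lace_estimates, nonlinear_mr,
                              piecewise_curve, quadratic_test, stratify)
from telomr.simulate import calibration_config, simulate_cohort, with_seed


def _grs(cohort):
    return build_grs(cohort.genotypes, {s: {1} for s in cohort.snp_ids})


class TestIVFreeExposure:
    def test_orthogonal_to_grs_in_fitting_set(self, linear_truth_cohort):
        cohort = linear_truth_cohort
        grs = _grs(cohort)
        ivf = iv_free_exposure(cohort, grs)
        ctrl = cohort.is_control().to_numpy()
        r = ivf.residuals.to_numpy()[ctrl]
        g = grs.to_numpy()[ctrl]
        assert abs(np.corrcoef(r, g)[0, 1]) < 1e-10
        assert abs(r.mean()) < 1e-10

    def test_zero_grs_effect_residual_is_centered_exposure(self):
        cfg = calibration_config(5000, 5000, delta=0.0, causal_shape="null", seed=3)
        cohort = simulate_cohort(cfg)
        grs = _grs(cohort)
        ivf = iv_free_exposure(cohort, grs, fit_on="all")
        x = cohort.exposure.to_numpy()
        # the estimated slope is pure noise, so the residual matches the
        # centered exposure up to that sampling noise
        rmse = np.sqrt(np.mean((ivf.residuals.to_numpy() - (x - x.mean())) ** 2))
        assert rmse < 0.05 * x.std()
        assert abs(ivf.coef["grs"]) < 3.5 / np.sqrt(cohort.n)  # ~3 SE of zero
        assert ivf.residuals.mean() == pytest.approx(0.0, abs=1e-10)

    def test_slope_recovery(self, linear_truth_cohort):
        ivf = iv_free_exposure(linear_truth_cohort, _grs(linear_truth_cohort))
        # each risk genotype lowers ln-exposure by 0.3 in this simulation
        assert ivf.coef["grs"] == pytest.approx(-0.3, abs=0.05)
        assert ivf.residuals.var() < linear_truth_cohort.exposure.var()

    def test_constant_grs_rejected(self, linear_truth_cohort):
        from telomr._glm import SingularDesignError

        flat = pd.Series(1.0, index=linear_truth_cohort.phenotypes.index)
        with pytest.raises(SingularDesignError):
            iv_free_exposure(linear_truth_cohort, flat)


class TestStratify:
    def test_even_split(self):
        labels = stratify(np.random.default_rng(0).normal(size=100), 5)
        assert sorted(np.bincount(labels)[1:]) == [20] * 5

    def test_split_at_median_for_k2(self):
        r = np.arange(10, dtype=float)
        labels = stratify(r, 2)
        assert (labels[:5] == 1).all() and (labels[5:] == 2).all()

    def test_uneven_sizes_differ_by_at_most_one(self):
        labels = stratify(np.random.default_rng(1).normal(size=103), 5)
        sizes = np.bincount(labels)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_ties_broken_by_stable_order(self):
        r = np.array([1.0, 1.0, 1.0, 2.0])
        labels = stratify(r, 2)
        assert list(labels) == [1, 1, 2, 2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            stratify(np.ones(50), 5)
        with pytest.raises(ValueError, match="at least 2"):
            stratify(np.arange(10.0), 1)

    def test_strata_partition_the_sample(self):
        r = np.random.default_rng(2).normal(size=997)
        labels = stratify(r, 7)
        assert len(labels) == 997 and set(labels) == set(range(1, 8))


class TestLACE:
    def test_single_stratum_equals_unstratified_ratio(self, linear_truth_cohort):
        import statsmodels.api as sm

        cohort = linear_truth_cohort
        grs = _grs(cohort)
        res = lace_estimates(cohort, grs, np.ones(cohort.n, dtype=int))
        g = grs.to_numpy()
        design = sm.add_constant(g)
        bx = sm.OLS(cohort.exposure.to_numpy(), design).fit().params[1]
        by = sm.Logit(cohort.outcome.to_numpy(), design).fit(disp=0, tol=1e-10).params[1]
        assert res[0].lace == pytest.approx(by / bx, abs=1e-10)

    def test_constant_lace_under_linear_truth(self, linear_truth_cohort):
        cohort = linear_truth_cohort
        grs = _grs(cohort)
        ivf = iv_free_exposure(cohort, grs)
        strata = stratify(ivf.residuals.to_numpy(), 5)
        res = lace_estimates(cohort, grs, strata)
        for s in res:
            assert s.lace == pytest.approx(0.3, abs=3.5 * s.se_lace)

    def test_lace_increases_under_quadratic_truth(self):
        """Convex causal effect: LACE rank-correlates positively with the
        stratum exposure mean in every replicate at this effect size."""
        cfg = calibration_config(10000, 10000, causal_shape="quadratic",
                                 theta=0.0, theta2=0.15)
        hits = 0
        for seed in range(10):
            cohort = simulate_cohort(with_seed(cfg, seed))
            grs = _grs(cohort)
            ivf = iv_free_exposure(cohort, grs)
            res = lace_estimates(cohort, grs, stratify(ivf.residuals.to_numpy(), 5))
            laces = [s.lace for s in res]
            means = [s.x_mean for s in res]
            hits += stats.spearmanr(means, laces).statistic > 0
        assert hits == 10

    def test_single_outcome_class_stratum_flagged(self, linear_truth_cohort):
        cohort = linear_truth_cohort
        grs = _grs(cohort)
        strata = stratify(iv_free_exposure(cohort, grs).residuals.to_numpy(), 5)
        # poison stratum 3: make it all-cases
        y = cohort.phenotypes["outcome"].copy()
        y[strata == 3] = 1
        poisoned = cohort.subset(np.ones(cohort.n, dtype=bool))
        poisoned.phenotypes = cohort.phenotypes.copy()
        poisoned.phenotypes["outcome"] = y
        res = lace_estimates(poisoned, grs, strata)
        assert res[2].excluded and not res[0].excluded


def _stratum(k, x_mean, lace, se, n=100, x_range=None):
    return StratumResult(k, n, x_mean, x_range or (x_mean - 0.5, x_mean + 0.5),
                         0.3, 0.02, lace * 0.3, se * 0.3, lace, se)


class TestQuadraticTest:
    def test_flat_profile_gives_zero_slope(self):
        res = quadratic_test([_stratum(k, 1.0 + k, 0.7, 0.2) for k in range(1, 6)])
        assert abs(res.slope) < 1e-10 and res.p_value == pytest.approx(1.0)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm

        strata = [_stratum(k, float(k), rng.normal(), rng.uniform(0.1, 0.5))
                  for k in range(1, 7)]
        res = quadratic_test(strata)
        x = np.array([s.x_mean for s in strata])
        lace = np.array([s.lace for s in strata])
        w = np.array([1 / s.se_lace**2 for s in strata])
        fit = sm.WLS(lace, sm.add_constant(x), weights=w).fit()
        assert res.slope == pytest.approx(fit.params[1], abs=1e-10)

    def test_requires_three_strata(self):
        with pytest.raises(ValueError, match="at least 3"):
            quadratic_test([_stratum(1, 1.0, 0.5, 0.1), _stratum(2, 2.0, 0.6, 0.1)])


class TestCochranQ:
    def test_identical_lace_q_zero(self):
        res = cochran_q_test([_stratum(k, float(k), 0.4, 0.3) for k in range(1, 5)])
        assert res.q == pytest.approx(0.0, abs=1e-12) and res.p_value == pytest.approx(1.0)

    def test_closed_form_two_strata(self):
        """LACE (0, 2) with equal SE 0.5: Q = 8 on 1 df, p ~ 0.0047."""
        res = cochran_q_test([_stratum(1, 1.0, 0.0, 0.5), _stratum(2, 2.0, 2.0, 0.5)])
        assert res.q == pytest.approx(8.0, abs=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.00468, abs=1e-4)

    def test_null_q_follows_chi_squared(self, rng):
        """Q computed from homogeneous Gaussian LACE draws follows
        chi-squared(K-1): KS not rejected at alpha = 0.01 over 500 replicates."""
        k, se = 5, 0.4
        qs = []
        for _ in range(500):
            laces = rng.normal(1.0, se, size=k)
            strata = [_stratum(j + 1, float(j), laces[j], se) for j in range(k)]
            qs.append(cochran_q_test(strata).q)
        assert stats.kstest(qs, stats.chi2(df=k - 1).cdf).pvalue > 0.01


class TestFracPoly:
    def test_constant_profile_selects_linear(self):
        res = fracpoly_test([_stratum(k, 1.0 + 0.4 * k, 0.7, 0.2)
                             for k in range(1, 6)])
        assert res.best_power == 1.0
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == 1.0

    def test_inverse_profile_selects_log(self):
        """LACE proportional to 1/x is the derivative of the logarithm: the
        selected power is 0."""
        xs = np.array([1.2, 1.6, 2.0, 2.4, 2.8])
        rng = np.random.default_rng(8)
        strata = [_stratum(k + 1, x, 2.0 / x + rng.normal(0, 1e-4), 0.05)
                  for k, x in enumerate(xs)]
        assert fracpoly_test(strata).best_power == 0.0

    def test_positivity_shift_recorded(self):
        strata = [_stratum(k, -2.0 + k, 0.5 + 0.1 * k, 0.2) for k in range(4)]
        res = fracpoly_test(strata)
        assert res.shift == pytest.approx(3.0)  # 1 - (-2)

    def test_antiderivative_matches_quadrature(self):
        for p in FRACPOLY_POWERS:
            num, _ = integrate.quad(lambda x: x ** (p - 1.0), 1.0, 3.0)
            ana = _fracpoly_antiderivative(3.0, p) - _fracpoly_antiderivative(1.0, p)
            assert ana == pytest.approx(num, abs=1e-6), p


class TestCurves:
    def test_piecewise_constant_slope_is_a_line(self):
        theta = 0.7
        strata = [_stratum(k, float(k), theta, 0.1,
                           x_range=(k - 0.5, k + 0.5)) for k in range(1, 6)]
        curve = piecewise_curve(strata, reference=3.0)
        np.testing.assert_allclose(curve.effect, theta * (curve.x - 3.0), atol=1e-10)

    def test_piecewise_continuity(self, rng):
        strata = [_stratum(k, float(k), rng.normal(), rng.uniform(0.1, 0.4),
                           x_range=(k - 0.5, k + 0.5)) for k in range(1, 6)]
        curve = piecewise_curve(strata, reference=1.0, points_per_segment=200)
        jumps = np.abs(np.diff(curve.effect))
        step = np.diff(curve.x).max()
        assert jumps.max() < 5 * step  # no discontinuities beyond local slope
        assert curve.effect[np.argmin(np.abs(curve.x - 1.0))] == pytest.approx(0.0, abs=1e-10)

    def test_reference_outside_range_rejected(self):
        strata = [_stratum(k, float(k), 0.5, 0.1) for k in range(1, 4)]
        with pytest.raises(ValueError, match="outside"):
            piecewise_curve(strata, reference=99.0)

    def test_fracpoly_curve_linear_power_is_straight(self):
        strata = [_stratum(k, float(k), 0.5, 0.1) for k in range(1, 6)]
        fp = fracpoly_test(strata)
        curve = fracpoly_curve(strata, fp, reference=2.0)
        slopes = np.diff(curve.effect) / np.diff(curve.x)
        np.testing.assert_allclose(slopes, slopes[0], atol=1e-8)

    def test_zero_coefficient_gives_flat_curve(self):
        from telomr.nonlinear import FracPolyTest

        strata = [_stratum(k, float(k), 0.0, 0.1) for k in range(1, 6)]
        fp = FracPolyTest(2.0, 0.0, 1.0, 0.0, 0.1, 0.0)
        curve = fracpoly_curve(strata, fp, reference=2.0)
        np.testing.assert_allclose(curve.effect, 0.0, atol=1e-12)

    def test_piecewise_covers_quadratic_truth(self):
        """Under a quadratic causal effect the fitted piecewise curve tracks
        the true h(x) within its 95% band at >= 90% of grid points."""
        theta2 = 0.15
        cfg = calibration_config(10000, 10000, causal_shape="quadratic",
                                 theta=0.0, theta2=theta2, seed=21)
        cohort = simulate_cohort(cfg)
        grs = _grs(cohort)
        nl = nonlinear_mr(cohort, grs, k=5, reference=0.0)
        curve = nl.curves["piecewise"]
        inside_band = 0
        truth = theta2 * curve.x**2  # h(x) - h(0)
        # compare only where the curve is supported by data (central strata)
        core = (curve.x > np.percentile(cohort.exposure, 5)) & (
            curve.x < np.percentile(cohort.exposure, 95))
        inside = (truth[core] >= curve.ci_low[core]) & (truth[core] <= curve.ci_high[core])
        assert inside.mean() >= 0.9


class TestFullNonlinearStage:
    def test_report_shapes(self, linear_truth_cohort):
        nl = nonlinear_mr(linear_truth_cohort, _grs(linear_truth_cohort), k=5)
        assert len(nl.strata) == 5
        assert sum(s.n for s in nl.strata) == linear_truth_cohort.n
        assert [s.x_mean for s in nl.strata] == sorted(s.x_mean for s in nl.strata)
        tests = nl.tests_frame()
        assert list(tests["test"]) == ["quadratic", "cochran_q", "fracpoly"]
        assert ((tests["p_value"] >= 0) & (tests["p_value"] <= 1)).all()

    def test_k_bounds(self, linear_truth_cohort):
        with pytest.raises(ValueError, match="between 2 and 10"):
            nonlinear_mr(linear_truth_cohort, _grs(linear_truth_cohort), k=1)
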