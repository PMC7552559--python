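"""Linear MR estimators: ratio/IVW, maximum likelihood, mode-based, rescaling."""

import math

import numpy as np
import pytest

from telomr.genetics import GenotypeCounts, contingency_or
from telomr.linear import (SummaryAssociations, ivw_estimate, mbe_estimate,
                           ml_estimate, or_per_10pct_decrease,
                           outcome_association, ratio_estimates)


def _summary(bx, sx, by, sy):
    ids = tuple(f"iv{i}" for i in range(len(bx)))
    return SummaryAssociations(ids, np.asarray(bx, float), np.asarray(sx, float),
                               np.asarray(by, float), np.asarray(sy, float))


def _random_summary(rng, j=8):
    bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    return _summary(bx, rng.uniform(0.01, 0.05, j),
                    rng.normal(0, 0.3, j), rng.uniform(0.05, 0.2, j))


class TestSummaryAssociations:
    def test_se_recovered_from_ci(self):
        s = SummaryAssociations.from_ci(
            ["a"], [-0.108], [(-0.204, -0.013)], [math.log(0.81)],
            [(math.log(0.58), math.log(1.12))],
        )
        assert s.se_x[0] == pytest.approx(0.0487, abs=1e-3)
        assert s.se_y[0] == pytest.approx(0.1679, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _summary([0.1], [0.0], [0.1], [0.1])
        with pytest.raises(ValueError, match="at least one"):
            SummaryAssociations((), np.array([]), np.array([]), np.array([]), np.array([]))

    def test_frame_round_trip(self, rng):
        s = _random_summary(rng)
        back = SummaryAssociations.from_frame(s.to_frame())
        np.testing.assert_allclose(back.beta_x, s.beta_x)
        np.testing.assert_allclose(back.se_y, s.se_y)


class TestOutcomeAssociation:
    def test_logistic_equals_contingency_or(self, strong_cohort):
        """Unadjusted over-dominant logistic OR matches the 2x2 cross-product
        ratio to 1e-6 (logistic/contingency equivalence)."""
        res = outcome_association(strong_cohort, "iv_a")
        g = strong_cohort.genotype("iv_a").to_numpy()
        y = strong_cohort.outcome.to_numpy()
        het = g == 1
        a = int(((y == 1) & het).sum())
        b = int(((y == 1) & ~het).sum())
        c = int(((y == 0) & het).sum())
        d = int(((y == 0) & ~het).sum())
        assert math.exp(res.effect) == pytest.approx(
            contingency_or(a, b, c, d).odds_ratio, abs=1e-6)

    def test_genotype_or_recovery(self):
        """A simulated direct genotype effect (no exposure path) is recovered
        within 3 Monte-Carlo SEs."""
        from telomr.simulate import calibration_config, simulate_cohort, with_seed

        # route the effect through a strong exposure path: beta_y per het is
        # theta * delta = 0.5 * -0.4 = -0.2
        cfg = calibration_config(5000, 5000, causal_shape="linear", theta=0.5,
                                 delta=-0.4, n_snps=1)
        betas = []
        for seed in range(40):
            cohort = simulate_cohort(with_seed(cfg, seed))
            betas.append(outcome_association(cohort, "iv1").effect)
        betas = np.asarray(betas)
        mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert betas.mean() == pytest.approx(-0.2, abs=3 * mc_se + 0.01)


class TestIVW:
    def test_single_instrument_is_plain_ratio(self):
        est = ivw_estimate(_summary([0.2], [0.02], [0.1], [0.05]))
        assert est.theta == pytest.approx(0.5, abs=1e-12)

    def test_identical_ratios_average_with_precision_gain(self):
        est = ivw_estimate(_summary([0.1, 0.2], [0.01, 0.01], [0.05, 0.10],
                                    [0.05, 0.05]))
        theta_j, se_j = ratio_estimates(
            _summary([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.05, 0.05]))
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        assert est.se < se_j.min()

    def test_published_summary_worked_example(self):
        """IVW on the published instrument summaries: theta ~ 1.66 (the crude,
        unadjusted combination of the two ratio estimates)."""
        from telomr.datasets import study_summary_associations

        est = ivw_estimate(study_summary_associations())
        assert est.theta == pytest.approx(1.66, abs=0.01)

    def test_equals_zero_intercept_wls(self, rng):
        """Algebraic identity: IVW theta equals the zero-intercept weighted
        least-squares slope of beta_y on beta_x with weights se_y^-2."""
        for _ in range(50):
            s = _random_summary(rng)
            w = 1.0 / s.se_y**2
            slope = (w * s.beta_x * s.beta_y).sum() / (w * s.beta_x**2).sum()
            assert ivw_estimate(s).theta == pytest.approx(slope, abs=1e-10)

    def test_zero_beta_x_rejected(self):
        with pytest.raises(ValueError, match="zero exposure association"):
            ivw_estimate(_summary([0.0, 0.1], [0.01, 0.01], [0.1, 0.1], [0.1, 0.1]))


class TestML:
    def test_single_instrument_matches_ratio(self):
        est = ml_estimate(_summary([0.2], [0.02], [0.1], [0.05]))
        assert est.theta == pytest.approx(0.5, abs=1e-6)

    def test_small_se_x_limit_equals_ivw(self, rng):
        s = _random_summary(rng)
        s2 = SummaryAssociations(s.snp_ids, s.beta_x, np.abs(s.beta_x) * 1e-6,
                                 s.beta_y, s.se_y)
        assert ml_estimate(s2).theta == pytest.approx(ivw_estimate(s2).theta,
                                                      rel=1e-4)

    def test_loglik_at_optimum_beats_ivw_point(self, rng):
        from telomr.linear import _ml_profile

        for _ in range(20):
            s = _random_summary(rng)
            est = ml_estimate(s)
            assert est.diagnostics["converged"]
            ll_opt, _ = _ml_profile(s, est.theta)
            ll_ivw, _ = _ml_profile(s, ivw_estimate(s).theta)
            assert ll_opt >= ll_ivw - 1e-9

    def test_recovery_on_summary_replicates(self, rng):
        """Mean ML estimate within 3 Monte-Carlo SEs of theta = 0.5 over 200
        summary-level replicates (10 instruments)."""
        theta = 0.5
        bx_true = np.linspace(0.08, 0.2, 10)
        est = []
        for _ in range(200):
            bx = rng.normal(bx_true, 0.02)
            by = rng.normal(theta * bx_true, 0.04)
            est.append(ml_estimate(_summary(bx, [0.02] * 10, by, [0.04] * 10)).theta)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert est.mean() == pytest.approx(theta, abs=3 * mc_se)


class TestMBE:
    def test_point_mass_returns_common_value(self):
        s = _summary([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.05] * 3)
        est = mbe_estimate(s, n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        assert est.diagnostics.get("zero_spread")

    def test_mode_robust_to_outlier(self):
        rng = np.random.default_rng(4)
        ratios = np.concatenate([rng.normal(1.0, 0.02, 9), [10.0]])
        s = _summary(np.full(10, 0.2), np.full(10, 0.02),
                     ratios * 0.2, np.full(10, 0.04))
        est = mbe_estimate(s, n_boot=50, seed=0)
        assert 0.8 <= est.theta <= 1.2

    def test_mode_matches_dense_grid_argmax(self, rng):
        """Returned mode agrees with an independent dense-grid argmax of the
        weighted kernel density to within one 1e-4 grid step."""
        from telomr.linear import _mbe_bandwidth

        for _ in range(5):
            s = _random_summary(rng, j=7)
            theta_j, se_j = ratio_estimates(s)
            w = 1.0 / se_j**2
            w = w / w.sum()
            h = _mbe_bandwidth(theta_j, 1.0)
            grid = np.arange(theta_j.min() - 3 * h, theta_j.max() + 3 * h, 1e-4)
            dens = (w[None, :] *
                    np.exp(-0.5 * ((grid[:, None] - theta_j[None, :]) / h) ** 2)
                    ).sum(axis=1)
            oracle = grid[np.argmax(dens)]
            est = mbe_estimate(s, n_boot=10, seed=0)
            assert abs(est.theta - oracle) <= 2e-4

    def test_two_instruments_flagged_degenerate(self):
        s = _summary([0.2, 0.1], [0.02, 0.02], [0.1, 0.08], [0.05, 0.05])
        with pytest.warns(UserWarning, match="fewer than 3"):
            est = mbe_estimate(s, n_boot=50, seed=0)
        assert "degenerate" in est.diagnostics

    def test_bootstrap_seeded(self):
        s = _summary([0.2, 0.1, 0.15, 0.3], [0.02] * 4,
                     [0.1, 0.08, 0.09, 0.2], [0.05] * 4)
        a = mbe_estimate(s, n_boot=100, seed=5)
        b = mbe_estimate(s, n_boot=100, seed=5)
        assert a.ci95 == b.ci95


class TestOrPer10PctDecrease:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, 1.0),
        (-2.576, 1.312),  # back-solves the published headline scale
        (1.0, 0.9),
    ])
    def test_examples(self, theta, expected):
        or_, _ = or_per_10pct_decrease(theta, se=0.1)
        assert or_ == pytest.approx(expected, abs=2e-3)

    def test_ci_reordered(self):
        _, ci = or_per_10pct_decrease(1.0, ci=(0.5, 1.5))
        assert ci[0] < ci[1]

    def test_alternative_convention(self):
        or_, _ = or_per_10pct_decrease(1.0, se=0.1, convention="div_1.1")
        assert or_ == pytest.approx(math.exp(-math.log(1.1)), abs=1e-12)


def test_all_estimators_equivariant_under_joint_sign_flip(rng):
    s = _random_summary(rng, j=6)
    flipped = SummaryAssociations(s.snp_ids, -s.beta_x, s.se_x, -s.beta_y, s.se_y)
    assert ivw_estimate(s).theta == pytest.approx(ivw_estimate(flipped).theta, abs=1e-12)
    assert ml_estimate(s).theta == pytest.approx(ml_estimate(flipped).theta, abs=1e-8)
    assert mbe_estimate(s, n_boot=20, seed=1).theta == pytest.approx(
        mbe_estimate(flipped, n_boot=20, seed=1).theta, abs=1e-10)
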