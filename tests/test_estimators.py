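"""Univariable MR estimators against hand computations, Monte-Carlo and
independent weighted-least-squares oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

import mrmediate as mm
from mrmediate.estimators import MREstimate
from helpers import make_harmonized


def random_fixture(rng, n=5, beta=0.3):
    bx = rng.normal(0.15, 0.05, n)
    bx[np.abs(bx) < 0.02] = 0.05
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.01, 0.05, n)
    by = beta * bx + rng.normal(0, sy)
    return make_harmonized(bx, sx, by, sy)


class TestWaldRatio:
    def test_zero_exposure_se_collapses_delta_term(self):
        est, se = mm.wald_ratio(0.5, 0.0, -0.25, 0.05)
        assert est == pytest.approx(-0.5)
        assert se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        est, _ = mm.wald_ratio(1.0, 0.01, 0.0, 0.05)
        assert est == 0.0

    def test_degenerate_instrument_raises(self):
        with pytest.raises(mm.DegenerateInstrumentError):
            mm.wald_ratio(0.0, 0.01, 0.1, 0.05)

    def test_se_matches_monte_carlo_sd(self, rng):
        bx, sx, by, sy = 0.5, 0.04, -0.2, 0.03
        _, se = mm.wald_ratio(bx, sx, by, sy)
        draws = rng.normal(by, sy, 1_000_000) / rng.normal(bx, sx, 1_000_000)
        assert se == pytest.approx(draws.std(), rel=0.02)


class TestIVW:
    def test_shared_ratio_recovered_with_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = -0.4 * bx
        h = make_harmonized(bx, 0.01, by, [0.02, 0.03, 0.04])
        est = mm.ivw(h)
        assert est.beta == pytest.approx(-0.4)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("mode", ["fixed", "multiplicative_random"])
    def test_matches_statsmodels_wls(self, rng, mode):
        h = random_fixture(rng)
        est = mm.ivw(h, mode=mode)
        w = 1.0 / h.se_outcome**2
        fit = sm.WLS(h.beta_outcome, h.beta_exposure, weights=w).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-12)
        model_se = fit.bse[0] / np.sqrt(fit.scale)  # unscaled (fixed-effect) SE
        if mode == "fixed":
            assert est.se == pytest.approx(model_se, rel=1e-10)
        else:
            q = float(fit.ssr)
            scale = max(q / (h.n_snp - 1), 1.0)
            assert est.se == pytest.approx(model_se * np.sqrt(scale), rel=1e-10)

    def test_equals_precision_weighted_mean_of_ratios(self, rng):
        for _ in range(20):
            h = random_fixture(rng, n=8)
            est = mm.ivw(h, mode="fixed")
            bx = h.beta_exposure[:, 0]
            w = bx**2 / h.se_outcome**2
            ratios = h.beta_outcome / bx
            assert est.beta == pytest.approx(np.sum(w * ratios) / np.sum(w), rel=1e-10)

    def test_parameter_recovery_summary_level(self, rng):
        """Mean IVW estimate over replicates is within 3 MC SEs of the truth."""
        truth, reps = -0.46, 200
        estimates = []
        for _ in range(reps):
            gamma = rng.normal(0.08, 0.02, 50)
            sx, sy = 0.01, 0.02
            bx = rng.normal(gamma, sx)
            by = rng.normal(truth * gamma, sy)
            est = mm.ivw(make_harmonized(bx, sx, by, sy))
            estimates.append(est.beta)
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(reps)
        assert abs(estimates.mean() - truth) < 3 * mc_se

    def test_insufficient_instruments(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(mm.InsufficientInstrumentsError):
            mm.ivw(h)


class TestEgger:
    def test_exact_line_recovered_to_machine_precision(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.02 + (-0.4) * bx
        h = make_harmonized(bx, 0.01, by, 0.05)
        est = mm.mr_egger(h)
        assert est.egger_intercept == pytest.approx(0.02, rel=1e-12)
        assert est.beta == pytest.approx(-0.4, rel=1e-12)

    def test_matches_statsmodels_wls_with_intercept(self, rng):
        h = random_fixture(rng, n=8)
        est = mm.mr_egger(h)
        # orientation: all bx positive in this fixture, so plain WLS applies
        assert (h.beta_exposure[:, 0] > 0).all()
        w = 1.0 / h.se_outcome**2
        X = sm.add_constant(h.beta_exposure)
        fit = sm.WLS(h.beta_outcome, X, weights=w).fit()
        assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)

    def test_slope_equals_ivw_when_intercept_constrained(self, rng):
        """Orientation alone does not move the origin-constrained fit."""
        h = random_fixture(rng, n=8)
        flip = np.sign(h.beta_exposure[:, 0])
        h_flipped = make_harmonized(
            h.beta_exposure[:, 0] * flip,
            h.se_exposure[:, 0],
            h.beta_outcome * flip,
            h.se_outcome,
        )
        assert mm.ivw(h_flipped).beta == pytest.approx(mm.ivw(h).beta, rel=1e-12)

    def test_balanced_pleiotropy_keeps_intercept_null(self, rng):
        """Intercept test retains the null in >= 90% of balanced-pleiotropy sims."""
        keep = 0
        reps = 500
        for _ in range(reps):
            n = 30
            gamma = rng.uniform(0.05, 0.15, n)
            sx, sy = 0.005, 0.02
            alpha = rng.normal(0.0, 0.02, n)  # balanced: zero mean
            bx = rng.normal(gamma, sx)
            by = rng.normal(-0.3 * gamma + alpha, sy)
            est = mm.mr_egger(make_harmonized(bx, sx, by, sy))
            keep += est.egger_intercept_pval > 0.05
        assert keep / reps >= 0.90

    def test_insufficient_instruments(self):
        h = make_harmonized([0.1, 0.2], 0.01, [0.0, 0.1], 0.02)
        with pytest.raises(mm.InsufficientInstrumentsError):
            mm.mr_egger(h)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        bx = np.ones(3)
        by = np.array([1.0, 2.0, 3.0])
        h = make_harmonized(bx, 0.01, by, 1.0)
        assert mm.weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(2.0)

    def test_equal_weight_interpolation(self):
        bx = np.ones(4)
        by = np.array([1.0, 2.0, 3.0, 10.0])
        h = make_harmonized(bx, 0.01, by, 1.0)
        # cumulative-midpoint quantiles 0.125/0.375/0.625/0.875 -> 2.5 at 0.5
        assert mm.weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(2.5)

    def test_bootstrap_se_deterministic_under_seed(self, rng):
        h = random_fixture(rng)
        a = mm.weighted_median(h, n_boot=200, seed=42)
        b = mm.weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se
        assert a.beta == b.beta

    @given(st.integers(0, 2**31 - 1))
    def test_estimate_within_ratio_range(self, seed):
        r = np.random.default_rng(seed)
        h = random_fixture(r, n=6)
        est = mm.weighted_median(h, n_boot=10, seed=0)
        ratios = h.beta_outcome / h.beta_exposure[:, 0]
        assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2])
        h = make_harmonized(bx, 0.01, 0.5 * bx, 0.02)
        q, df, p = mm.cochran_q(h, 0.5)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert (df, p) == (1, 1.0)

    def test_hand_computed_two_variant_case(self):
        # ratios 0 and 1 with unit weights around center 0.5: Q = 0.5
        bx = np.array([1.0, 1.0])
        by = np.array([0.0, 1.0])
        h = make_harmonized(bx, 0.0001, by, 1.0)
        q, df, _ = mm.cochran_q(h, 0.5)
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_invariant_to_global_sign_flip(self, rng):
        h = random_fixture(rng)
        q1, _, _ = mm.cochran_q(h, 0.3)
        h_flip = make_harmonized(
            -h.beta_exposure[:, 0], h.se_exposure[:, 0], -h.beta_outcome, h.se_outcome
        )
        q2, _, _ = mm.cochran_q(h_flip, 0.3)
        assert q1 == pytest.approx(q2, rel=1e-12)


class TestOddsRatio:
    def test_null_effect_gives_unit_or(self):
        e = MREstimate("ivw_mre", 0.0, 0.1, -0.196, 0.196, 1.0, 5, outcome_binary=True)
        assert mm.to_odds_ratio(e).odds_ratio == 1.0

    def test_reporting_convention_round_trip(self):
        # log-odds -0.459 (SE 0.157) -> OR 0.632, 95% CI ~[0.464, 0.860].
        # 1e-3 tolerance: published CIs are computed from unrounded estimates,
        # so recomputation from 3-dp inputs can shift the last digit.
        e = MREstimate("ivw_mre", -0.459, 0.157, 0, 0, 0.003, 30, outcome_binary=True)
        orr = mm.to_odds_ratio(e)
        assert orr.odds_ratio == pytest.approx(0.632, abs=1e-3)
        assert orr.ci_low == pytest.approx(0.464, abs=1e-3)
        assert orr.ci_high == pytest.approx(0.860, abs=1e-3)
        assert np.log(orr.odds_ratio) == pytest.approx(e.beta)

    def test_unit_error_on_continuous_outcome(self):
        e = MREstimate("ivw_mre", 0.1, 0.1, -0.1, 0.3, 0.5, 5, outcome_binary=False)
        with pytest.raises(mm.UnitError):
            mm.to_odds_ratio(e)
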