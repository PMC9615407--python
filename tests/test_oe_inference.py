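"""O/E ratios, random-effects Poisson pooling, arm contrasts, REML."""

import numpy as np
import pytest
from scipy import stats

from saeratio.expectation import ExpectedCount
from saeratio.oe_inference import (
    arm_log_rate_ratio,
    meta_analyze,
    oe_ratio,
    pool_oe,
)
from saeratio.trial_reconstruction import ArmRow, TrialSummary


def _exp(expected, draws=None):
    return ExpectedCount(trial_id="t", expected=expected, basis="age_sex",
                         person_time_days=1.0, draws=draws)


class TestOERatio:
    def test_point_ratio_is_division(self):
        est = oe_ratio(60, _exp(100.0), n_draws=2_000, seed=1)
        assert est.ratio == pytest.approx(0.60)
        assert est.lower <= est.ratio <= est.upper

    def test_symmetric_interval_contains_one_for_large_null_count(self):
        est = oe_ratio(400, _exp(400.0), n_draws=5_000, seed=2)
        assert est.lower < 1.0 < est.upper

    def test_zero_observed_interval_matches_gamma_reference(self):
        # Jeffreys draws at O=0 are Gamma(0.5, 1); with a degenerate
        # expected count the interval endpoints, pushed through the exact
        # Gamma CDF, must sit at 2.5% and 97.5% (1e-3 on probability, the
        # attainable precision of a 10^6-draw interval)
        E = 10.0
        est = oe_ratio(0, _exp(E), n_draws=1_000_000, seed=3)
        assert est.ratio == 0.0
        assert est.upper > 0.0
        for endpoint, p in [(est.lower, 0.025), (est.upper, 0.975)]:
            assert stats.gamma.cdf(endpoint * E, a=0.5) == pytest.approx(
                p, abs=1e-3
            )

    def test_expected_zero_is_informative_error(self):
        with pytest.raises(ZeroDivisionError, match="expected count is zero"):
            oe_ratio(5, _exp(0.0))

    def test_expected_draws_widen_interval(self):
        rng = np.random.default_rng(4)
        draws = 100.0 * np.exp(rng.normal(0, 0.1, size=4_000))
        narrow = oe_ratio(80, _exp(100.0), n_draws=4_000, seed=5)
        wide = oe_ratio(80, _exp(100.0, draws=draws), n_draws=4_000, seed=5)
        assert (wide.upper - wide.lower) > (narrow.upper - narrow.lower)


_GL_NODES = np.polynomial.legendre.leggauss(240)


def _marginal_loglik_gl(theta, tau, obs, exp_):
    """Independent oracle: marginal log likelihood by fixed Gauss-Legendre
    quadrature over the random effect (no Laplace centring, no Hermite rule)."""
    total = 0.0
    x, w = _GL_NODES
    for o, e in zip(obs, exp_):
        if tau < 1e-10:
            total += stats.poisson.logpmf(o, e * np.exp(theta))
            continue
        b = 8.0 * tau * x  # integrate over [-8 tau, 8 tau]
        lam = e * np.exp(theta + b)
        f = stats.poisson.pmf(o, lam) * stats.norm.pdf(b, 0, tau)
        total += np.log(np.sum(w * f) * 8.0 * tau)
    return total


class TestPoolOE:
    def test_single_trial_passes_through(self):
        p = pool_oe([(30, 60.0)], condition="copd")
        assert p.ratio == pytest.approx(0.5)
        assert p.tau == 0.0
        assert p.k == 1

    def test_null_large_counts(self):
        p = pool_oe([(400, 400.0)] * 20)
        assert p.lower < 1.0 < p.upper
        assert p.tau < 0.05

    def test_matches_grid_search_oracle(self):
        # small instance: dense (theta, tau) grid over the independent
        # quadrature likelihood, refined to 1e-3 resolution
        obs, exp_ = [5.0, 10.0, 20.0], [10.0, 10.0, 10.0]
        p = pool_oe(list(zip(obs, exp_)))

        def grid_max(thetas, taus):
            best = (-np.inf, None, None)
            for th in thetas:
                for ta in taus:
                    ll = _marginal_loglik_gl(th, ta, obs, exp_)
                    if ll > best[0]:
                        best = (ll, th, ta)
            return best

        # coarse grid, then local refinement at 1e-3 resolution
        _, th0, ta0 = grid_max(np.arange(-0.4, 0.8, 0.04),
                               np.arange(0.0, 1.0, 0.04))
        _, th, ta = grid_max(np.arange(th0 - 0.05, th0 + 0.05, 1e-3),
                             np.arange(max(ta0 - 0.05, 0.0), ta0 + 0.05, 1e-3))
        assert p.log_ratio == pytest.approx(th, abs=2e-3)
        assert p.tau == pytest.approx(ta, abs=2e-3)

    def test_scale_equivariance(self):
        pairs = [(12, 10.0), (8, 9.0), (15, 11.0), (20, 14.0)]
        c = 3.0
        p1 = pool_oe(pairs)
        p2 = pool_oe([(o, c * e) for o, e in pairs])
        assert p2.ratio == pytest.approx(p1.ratio / c, rel=1e-4)
        assert p2.lower == pytest.approx(p1.lower / c, rel=1e-3)
        assert p2.tau == pytest.approx(p1.tau, abs=1e-3)

    def test_bootstrap_interval_option(self):
        pairs = [(12, 10.0), (8, 9.0), (15, 11.0), (20, 14.0)]
        p = pool_oe(pairs, interval="bootstrap", n_boot=200, seed=9)
        assert p.lower < p.ratio < p.upper

    def test_rejects_nonpositive_expected(self):
        with pytest.raises(ValueError):
            pool_oe([(5, 0.0)])


def _summary_with_arms(arms, trial_id="t1", fu=182.0):
    n = sum(a.n for a in arms)
    return TrialSummary(
        trial_id=trial_id, condition="copd", n_participants=n,
        age_mean=65.0, age_sd=8.0, age_min=45.0, age_max=85.0,
        percent_female=50.0, followup_days=fu,
        sae_count=sum(a.sae_count for a in arms), arms=arms,
    )


class TestArmLogRateRatio:
    def test_equal_rates_give_zero(self):
        s = _summary_with_arms((
            ArmRow("a", "placebo", 100, 10), ArmRow("b", "experimental", 100, 10),
        ))
        cmp = arm_log_rate_ratio(s)
        assert cmp.comparison == "placebo"
        assert cmp.log_rate_ratio == pytest.approx(0.0)
        assert cmp.se == pytest.approx(np.sqrt(0.2))

    def test_doubled_rate_gives_log_two(self):
        # person-times equalised by matching event-corrected exposure
        s = _summary_with_arms((
            ArmRow("ctrl", "placebo", 105, 10),  # PT = fu*(105-5) = fu*100
            ArmRow("trt", "experimental", 110, 20),  # PT = fu*(110-10) = fu*100
        ))
        cmp = arm_log_rate_ratio(s)
        assert cmp.log_rate_ratio == pytest.approx(np.log(2.0))

    def test_zero_count_continuity_correction(self):
        s = _summary_with_arms((
            ArmRow("ctrl", "placebo", 100, 0), ArmRow("trt", "experimental", 100, 5),
        ))
        cmp = arm_log_rate_ratio(s)
        assert cmp.continuity_corrected
        # equal nominal PT up to the event correction; the corrected point
        # estimate ln((5.5/PT2)/(0.5/PT1)) must lie inside the exact
        # conditional mid-p interval for the split 5:0 of 5 events
        # (lower bound: 0.5*P(X=5|p)=0.025 -> p=0.1^(1/5), RR=p/(1-p))
        p_low = 0.1 ** (1 / 5)
        rr_low = p_low / (1 - p_low)
        assert cmp.log_rate_ratio > np.log(rr_low)
        est_no_pt = np.log(5.5 / 0.5)
        assert cmp.log_rate_ratio == pytest.approx(est_no_pt, abs=0.05)

    def test_single_arm_rejected(self):
        s = _summary_with_arms((ArmRow("only", "experimental", 100, 5),))
        with pytest.raises(ValueError, match="two arms"):
            arm_log_rate_ratio(s)

    def test_experimental_vs_active_designation(self):
        s = _summary_with_arms((
            ArmRow("a", "active", 100, 10), ArmRow("e", "experimental", 100, 12),
        ))
        assert arm_log_rate_ratio(s).comparison == "experimental-vs-active"


def _reml_nll_grid(tau2, y, v):
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return (0.5 * np.sum(np.log(v + tau2)) + 0.5 * np.log(np.sum(w))
            + 0.5 * np.sum(w * (y - mu) ** 2))


class TestMetaAnalyze:
    def test_identical_effects_give_zero_tau2(self):
        m = meta_analyze([(0.3, 0.1)] * 4)
        assert m.estimate == pytest.approx(0.3)
        assert m.tau2 == 0.0

    def test_single_effect_passes_through(self):
        m = meta_analyze([(0.2, 0.05)])
        assert m.passthrough
        assert m.estimate == pytest.approx(0.2)
        assert m.se == pytest.approx(0.05)

    def test_two_study_tau2_matches_grid_oracle(self):
        y = np.array([0.0, 0.5])
        v = np.array([0.01, 0.01])
        m = meta_analyze([(0.0, 0.1), (0.5, 0.1)])
        grid = np.arange(0.0, 2.0, 1e-4)
        vals = [_reml_nll_grid(t, y, v) for t in grid]
        tau2_grid = grid[int(np.argmin(vals))]
        assert m.tau2 == pytest.approx(tau2_grid, abs=2e-4)

    def test_rejects_invalid_se(self):
        with pytest.raises(ValueError):
            meta_analyze([(0.1, 0.0), (0.2, 0.1)])
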