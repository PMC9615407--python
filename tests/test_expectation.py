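"""Indirect standardization: person-time formula and expected counts."""

import numpy as np
import pandas as pd
import pytest

from saeratio.expectation import (
    ExpectedCount,
    aggregate_person_time,
    expected_events_aggregate,
    expected_events_ipd,
)
from saeratio.ipd_pipeline import TrialIPD
from saeratio.rate_models import RateModel, RateModelError, default_age_spec
from saeratio.trial_reconstruction import AgeSexDistribution


def constant_rate_model(rate_per_day: float, sex: str = "male") -> RateModel:
    """Intercept-only model with a zero age slope: rate r at every age."""
    return RateModel(
        sex=sex,
        condition="copd",
        specs={"age": default_age_spec()},
        params=np.array([np.log(rate_per_day), 0.0]),
        cov=np.zeros((2, 2)),
        age_support=(18.0, 99.0),
    )


def uniform_dist(lo: int, hi: int, percent_female: float = 50.0):
    bands = np.arange(lo, hi)
    w = pd.Series(np.full(len(bands), 1.0 / len(bands)), index=bands)
    pf = percent_female / 100.0
    return AgeSexDistribution(
        weights={"male": w, "female": w.copy()},
        sex_proportions={"male": 1 - pf, "female": pf},
    )


class TestAggregatePersonTime:
    @pytest.mark.parametrize(
        "n, fu, events, expected",
        [(100, 182.0, 0, 18_200.0), (100, 182.0, 10, 17_290.0),
         (100, 182.0, 100, 9_100.0), (500, 182.0, 0, 91_000.0)],
    )
    def test_formula_cases(self, n, fu, events, expected):
        assert aggregate_person_time(n, fu, events) == pytest.approx(expected)

    def test_events_above_n_floored_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            pt = aggregate_person_time(100, 182.0, 150)
        assert pt == pytest.approx(9_100.0)
        assert "floored" in caplog.text

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_person_time(0, 182.0, 0)
        with pytest.raises(ValueError):
            aggregate_person_time(10, 182.0, -1)


class TestExpectedAggregate:
    def test_constant_rate_collapses_to_rate_times_person_time(self):
        r = 1e-3
        models = {"male": constant_rate_model(r, "male"),
                  "female": constant_rate_model(r, "female")}
        dist = uniform_dist(50, 80, percent_female=40.0)
        exp = expected_events_aggregate(models, dist, 200, 182.0, 12)
        pt = aggregate_person_time(200, 182.0, 12)
        assert exp.expected == pytest.approx(r * pt, rel=1e-12)
        assert exp.person_time_days == pytest.approx(pt)

    def test_zero_weight_band_is_irrelevant(self, models_age_sex):
        dist = uniform_dist(60, 70)
        w = dist.weights["male"]
        with_zero = pd.concat([w, pd.Series([0.0], index=[75])])
        dist2 = AgeSexDistribution(
            weights={"male": with_zero, "female": with_zero.copy()},
            sex_proportions=dist.sex_proportions,
        )
        e1 = expected_events_aggregate(models_age_sex, dist, 100, 182.0, 5)
        e2 = expected_events_aggregate(models_age_sex, dist2, 100, 182.0, 5)
        assert e1.expected == pytest.approx(e2.expected, rel=1e-12)

    def test_matches_brute_force_cell_enumeration(self, models_age_sex):
        # independent oracle: python loop over every (sex, band) cell
        dist = uniform_dist(55, 85, percent_female=47.0)
        n, fu, events = 300, 182.0, 40
        exp = expected_events_aggregate(models_age_sex, dist, n, fu, events)

        cells = []
        for sex, prop in dist.sex_proportions.items():
            for band, weight in dist.weights[sex].items():
                rate = float(models_age_sex[sex].predict_rate(float(band))[0])
                cells.append((prop * weight, rate))
        share = sum(wp * r for wp, r in cells)
        deficit = 0.5 * fu * events
        brute = sum(
            r * (fu * n * wp - deficit * wp * r / share) for wp, r in cells
        )
        assert exp.expected == pytest.approx(brute, rel=1e-9)

    def test_missing_sex_model_raises(self, models_age_sex):
        dist = uniform_dist(60, 70)
        with pytest.raises(RateModelError, match="female"):
            expected_events_aggregate(
                {"male": models_age_sex["male"]}, dist, 100, 182.0, 0
            )

    def test_draw_mean_converges_to_point(self, models_age_sex):
        dist = uniform_dist(60, 80)
        exp = expected_events_aggregate(
            models_age_sex, dist, 500, 182.0, 30, n_draws=10_000, seed=5
        )
        mc_se = exp.draws.std() / np.sqrt(len(exp.draws))
        # allow the second-order lognormal offset exp(var/2) of exp-normal
        # draws on top of Monte-Carlo error
        lp_var = (np.log(exp.draws)).var()
        bias = exp.expected * (np.exp(lp_var / 2) - 1.0)
        assert abs(exp.draws.mean() - exp.expected) < 3 * mc_se + bias


class TestExpectedIPD:
    def _ipd(self, rows):
        return TrialIPD(
            trial_id="t", condition="copd",
            df=pd.DataFrame(rows, columns=["age", "sex", "arm", "mm_count",
                                           "followup_days", "sae"]),
        )

    def test_single_participant_rate_times_exposure(self):
        r = 2e-3
        models = {"male": constant_rate_model(r), "female": constant_rate_model(r, "female")}
        ipd = self._ipd([[70, "male", "control", 2, 120.0, 0]])
        exp = expected_events_ipd(models, ipd)
        assert exp.expected == pytest.approx(r * 120.0, rel=1e-12)

    def test_permutation_invariance(self, models_age_sex):
        rng = np.random.default_rng(6)
        rows = [[int(a), s, "control", 1, float(f), 0]
                for a, s, f in zip(rng.integers(50, 90, 40),
                                   rng.choice(["male", "female"], 40),
                                   rng.uniform(30, 182, 40))]
        e1 = expected_events_ipd(models_age_sex, self._ipd(rows))
        e2 = expected_events_ipd(models_age_sex, self._ipd(rows[::-1]))
        assert e1.expected == pytest.approx(e2.expected, rel=1e-12)

    def test_linearity_over_pooled_trials(self, models_age_sex, trial_suite):
        _, ipds = trial_suite
        a, b = ipds[0], ipds[1]
        pooled = TrialIPD(
            trial_id="ab", condition="copd",
            df=pd.concat([a.df, b.df], ignore_index=True),
        )
        ea = expected_events_ipd(models_age_sex, a).expected
        eb = expected_events_ipd(models_age_sex, b).expected
        eab = expected_events_ipd(models_age_sex, pooled).expected
        assert eab == pytest.approx(ea + eb, rel=1e-9)

    def test_mm_basis_requires_mm_model(self, models_age_sex, trial_suite):
        _, ipds = trial_suite
        with pytest.raises(RateModelError, match="multimorbidity"):
            expected_events_ipd(models_age_sex, ipds[0], basis="age_sex_mm")

    def test_mm_basis_lower_when_trial_mm_below_cohort(
        self, models_age_sex, models_age_sex_mm
    ):
        # every participant at mm=0, far below the register's age-matched
        # mean, with a positive mm coefficient: adding mm lowers expected
        rows = [[75, "male", "control", 0, 182.0, 0] for _ in range(50)]
        e_as = expected_events_ipd(models_age_sex, self._ipd(rows)).expected
        e_mm = expected_events_ipd(
            models_age_sex_mm, self._ipd(rows), basis="age_sex_mm"
        ).expected
        assert e_mm < e_as


def test_expected_count_validation():
    with pytest.raises(ValueError):
        ExpectedCount(trial_id="t", expected=-1.0, basis="age_sex",
                      person_time_days=10.0)
    with pytest.raises(ValueError):
        ExpectedCount(trial_id="t", expected=1.0, basis="weird",
                      person_time_days=10.0)
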