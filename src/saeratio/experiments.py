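"""Simulation studies validating the observed/expected SAE pipeline.

Each study regenerates its own synthetic data per replicate — a fresh
condition register (a single-condition routine-care cohort, as a register
of 100,000 patients with the index condition) and a fresh trial suite —
so that reference-rate estimation error varies across replicates instead
of being shared by them.  Mirroring the real setting, where the
routine-care reference dwarfs any trial, the register is large enough
that rate-model uncertainty is second-order relative to trial sampling
noise.

Studies:

- :func:`calibration_study` — null selection with hazard multiplier
  theta = 1: pooled and per-trial interval coverage of the truth.
- :func:`recovery_study` — planted theta: bias of the pooled ratio and
  the rate at which pooled intervals exclude the null.
- :func:`decomposition_study` — multimorbidity-biased selection: the
  age/sex-standardized pooled ratio falls below theta while the
  age/sex/multimorbidity ratio recovers it.
- :func:`model_recovery_study` — fractional-polynomial rate-curve RMSE
  against the analytic marginal rate, and pooled recovery of the planted
  multimorbidity log rate ratio from trial IPD.

The replicate studies fix linear age (and multimorbidity) terms — the
generating model's own functional form — so they isolate the property
under study from power-selection variability; power selection itself is
exercised by :func:`model_recovery_study` and the unit tests.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from saeratio.expectation import expected_events_aggregate
from saeratio.ipd_pipeline import dual_standardization, mm_sae_association
from saeratio.oe_inference import meta_analyze, oe_ratio, pool_oe
from saeratio.rate_models import fit_rate_model_pair
from saeratio.synthetic_data import (
    DAYS_PER_YEAR,
    CohortConfig,
    ConditionProfile,
    SelectionModel,
    generate_cohort,
    generate_trial_suite,
)
from saeratio.trial_reconstruction import reconstruct_age_distribution

#: Study condition: a COPD-like register (age 69.1 +/- 11.6 y, ~3 chronic
#: comorbidities at the mean age).
STUDY_CONDITION = "copd"
STUDY_PROFILE = ConditionProfile(
    STUDY_CONDITION, 1.0, 69.1, 11.6, mm_mean_at_50=2.0, mm_slope_per_decade=0.5
)


def study_cohort_config(n_persons: int, seed: int) -> CohortConfig:
    """Configuration of one replicate's condition register."""
    return CohortConfig(
        n_persons=n_persons,
        condition_profiles=(STUDY_PROFILE,),
        seed=seed,
    )


def _replicate_oe(
    rep_seed: int,
    *,
    cohort_n: int,
    n_trials: int,
    n_per_trial: int,
    selection: SelectionModel,
    followup_days: float = 182.0,
    n_draws: int = 0,
):
    """One replicate of the aggregate-data pipeline: cohort -> models ->
    trials -> reconstruction -> expectation -> per-trial estimates -> pool."""
    cohort = generate_cohort(study_cohort_config(cohort_n, rep_seed))
    models = fit_rate_model_pair(
        cohort, STUDY_CONDITION, {"age"}, select_powers=False
    )
    summaries, _ = generate_trial_suite(
        cohort, STUDY_CONDITION, selection, n_trials, n_per_trial,
        followup_days, seed=rep_seed + 1,
    )
    # one shared set of coefficient samples per sex model, so expected-count
    # uncertainty correlates across trials exactly as the fitted model's does
    s_draws = max(n_draws, 400)
    draw_rng = np.random.default_rng(rep_seed + 2)
    coef_draws = {
        sex: m.coefficient_draws(s_draws, draw_rng) for sex, m in models.items()
    }
    pairs, estimates = [], []
    total_draws = np.zeros(s_draws)
    for i, s in enumerate(summaries):
        dist = reconstruct_age_distribution(s)
        exp = expected_events_aggregate(
            models, dist, s.n_participants, s.followup_days, s.sae_count,
            trial_id=s.trial_id, coef_draws=coef_draws,
        )
        pairs.append((s.sae_count, exp.expected))
        total_draws += exp.draws
        if n_draws > 0:
            estimates.append(
                oe_ratio(s.sae_count, exp, n_draws=s_draws,
                         seed=rep_seed + 101 * i + 50)
            )
    pooled = pool_oe(
        pairs, condition=STUDY_CONDITION,
        log_expected_se=float(np.std(np.log(total_draws))),
    )
    return pooled, estimates


def calibration_study(
    seed: int,
    *,
    n_reps: int = 200,
    cohort_n: int = 100_000,
    n_trials: int = 20,
    n_per_trial: int = 500,
    n_draws: int = 1_000,
) -> dict:
    """Null calibration: theta = 1, representative sampling.

    Returns pooled-interval coverage of 1, per-trial interval coverage of
    the true per-trial ratio (also 1), and the mean pooled ratio.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    covered_pool = 0
    covered_trial = 0
    n_trial_total = 0
    ratios = []
    for rs in rep_seeds:
        pooled, estimates = _replicate_oe(
            int(rs), cohort_n=cohort_n, n_trials=n_trials,
            n_per_trial=n_per_trial, selection=SelectionModel(),
            n_draws=n_draws,
        )
        ratios.append(pooled.ratio)
        covered_pool += pooled.lower <= 1.0 <= pooled.upper
        for est in estimates:
            covered_trial += est.lower <= 1.0 <= est.upper
            n_trial_total += 1
    return {
        "n_reps": n_reps,
        "pooled_coverage": covered_pool / n_reps,
        "per_trial_coverage": covered_trial / n_trial_total,
        "mean_pooled_ratio": float(np.mean(ratios)),
        "sd_pooled_ratio": float(np.std(ratios)),
    }


def recovery_study(
    seed: int,
    theta: float,
    *,
    n_reps: int = 25,
    cohort_n: int = 100_000,
    n_trials: int = 50,
    n_per_trial: int = 500,
) -> dict:
    """Planted-theta recovery: pooled ratio bias and null-exclusion rate."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    ratios, excludes = [], 0
    for rs in rep_seeds:
        pooled, _ = _replicate_oe(
            int(rs), cohort_n=cohort_n, n_trials=n_trials,
            n_per_trial=n_per_trial,
            selection=SelectionModel(rate_multiplier=theta,
                                     label=f"theta={theta}"),
        )
        ratios.append(pooled.ratio)
        excludes += pooled.upper < 1.0 or pooled.lower > 1.0
    return {
        "theta": theta,
        "n_reps": n_reps,
        "mean_pooled_ratio": float(np.mean(ratios)),
        "sd_pooled_ratio": float(np.std(ratios)),
        "frac_excluding_null": excludes / n_reps,
    }


def decomposition_study(
    seed: int,
    theta: float = 1.0,
    *,
    mm_penalty: float = -0.35,
    n_reps: int = 25,
    cohort_n: int = 100_000,
    n_trials: int = 20,
    n_per_trial: int = 500,
    n_draws: int = 500,
) -> dict:
    """Multimorbidity-biased selection and the dual standardization.

    Trials under-sample multimorbid patients (inclusion log odds
    ``mm_penalty`` per condition) while the hazard multiplier is theta.
    Age/sex standardization alone then under-states theta; adding the
    multimorbidity count to the standardization recovers it.  Reported:
    mean pooled ratio on each basis and the fraction of trials in which
    the multimorbidity-adjusted ratio exceeds the age/sex ratio.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    pooled_as, pooled_mm = [], []
    n_dir = 0
    n_trials_total = 0
    for rs in rep_seeds:
        rs = int(rs)
        cohort = generate_cohort(study_cohort_config(cohort_n, rs))
        m_as = fit_rate_model_pair(
            cohort, STUDY_CONDITION, {"age"}, select_powers=False
        )
        m_mm = fit_rate_model_pair(
            cohort, STUDY_CONDITION, {"age", "mm_count"}, select_powers=False
        )
        sel = SelectionModel(
            rate_multiplier=theta, mm_penalty=mm_penalty, label="mm-biased"
        )
        _, ipds = generate_trial_suite(
            cohort, STUDY_CONDITION, sel, n_trials, n_per_trial, 182.0,
            seed=rs + 1,
        )
        pairs_as, pairs_mm = [], []
        for i, trial in enumerate(ipds):
            d = dual_standardization(
                trial, m_as, m_mm, n_draws=n_draws, seed=rs + 7 * i
            )
            pairs_as.append((trial.observed_sae, d.ratio_age_sex.expected))
            pairs_mm.append((trial.observed_sae, d.ratio_age_sex_mm.expected))
            n_dir += d.ratio_age_sex_mm.ratio > d.ratio_age_sex.ratio
            n_trials_total += 1
        pooled_as.append(pool_oe(pairs_as).ratio)
        pooled_mm.append(pool_oe(pairs_mm).ratio)
    return {
        "theta": theta,
        "mm_penalty": mm_penalty,
        "n_reps": n_reps,
        "mean_pooled_ratio_age_sex": float(np.mean(pooled_as)),
        "mean_pooled_ratio_age_sex_mm": float(np.mean(pooled_mm)),
        "frac_mm_above_age_sex": n_dir / n_trials_total,
    }


def true_marginal_rate(
    age_band: float, sex: str, config: CohortConfig
) -> float:
    """Analytic person-time-weighted marginal SAE rate for one age band.

    Marginalizes the generator's hazard over the Poisson multimorbidity
    distribution at the band midpoint, weighting by expected time at risk
    — the quantity the sex-stratified age-only rate model estimates.
    """
    profile = config.condition_profiles[0]
    age = age_band + 0.5  # recorded age a stands for [a, a+1)
    lam = max(
        0.0,
        profile.mm_mean_at_50
        + profile.mm_slope_per_decade * (age - 50.0) / 10.0,
    )
    mms = np.arange(0, 21)
    pm = stats.poisson.pmf(mms, lam)
    pm[-1] += max(0.0, 1.0 - pm.sum())
    female = 1.0 if sex == "female" else 0.0
    h = (
        config.baseline_rate
        / DAYS_PER_YEAR
        * np.exp(
            config.age_log_rr_per_decade * (age - config.reference_age) / 10.0
            + config.sex_log_rr * female
            + config.mm_log_rr_per_condition * mms
        )
    )
    tau = config.observation_days
    expected_events = pm * (1.0 - np.exp(-h * tau))
    expected_time = expected_events / h
    return float(expected_events.sum() / expected_time.sum())


def model_recovery_study(
    seed: int,
    *,
    cohort_n: int = 100_000,
    n_trials: int = 30,
    n_per_trial: int = 500,
    age_lo: int = 40,
    age_hi: int = 90,
) -> dict:
    """Rate-curve and multimorbidity-coefficient recovery.

    Fits the sex-stratified rate models with full fractional-polynomial
    power selection and reports the log-scale RMSE of the fitted curve
    against :func:`true_marginal_rate` over ages ``age_lo``..``age_hi``,
    plus the REML-pooled multimorbidity coefficient from per-trial,
    per-sex IPD Poisson fits (planted value: the generator's
    ``mm_log_rr_per_condition``).
    """
    config = study_cohort_config(cohort_n, seed)
    cohort = generate_cohort(config)
    models = fit_rate_model_pair(
        cohort, STUDY_CONDITION, {"age"}, select_powers=True
    )
    ages = np.arange(age_lo, age_hi + 1, dtype=float)
    rmse = {}
    for sex, model in models.items():
        fitted = np.log(model.predict_rate(ages))
        truth = np.log([true_marginal_rate(a, sex, config) for a in ages])
        rmse[sex] = float(np.sqrt(np.mean((fitted - truth) ** 2)))

    _, ipds = generate_trial_suite(
        cohort, STUDY_CONDITION, SelectionModel(), n_trials, n_per_trial,
        182.0, seed=seed + 1,
    )
    effects = []
    for trial in ipds:
        for sex in ("male", "female"):
            assoc = mm_sae_association(trial, sex)
            if assoc is not None:
                effects.append((assoc.coef, assoc.se))
    pooled = meta_analyze(effects)
    return {
        "log_rmse_male": rmse["male"],
        "log_rmse_female": rmse["female"],
        "selected_powers": {
            sex: list(m.specs["age"].powers) for sex, m in models.items()
        },
        "mm_coef_pooled": pooled.estimate,
        "mm_coef_se": pooled.se,
        "mm_coef_k": pooled.k,
        "planted_mm_coef": config.mm_log_rr_per_condition,
    }
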