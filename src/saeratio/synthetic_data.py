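"""Synthetic routine-care cohorts and trial suites with known ground truth.

The generator emulates the statistical structure the observed/expected SAE
analysis assumes: a routine-care cohort in which the hazard of a first
urgent hospitalisation or death is log-linear in age, sex and
multimorbidity count, and suites of trials whose participants are drawn
from that cohort through a selection mechanism that can under-sample older
and high-multimorbidity people, and whose SAE hazard can be scaled by a
known multiplier theta (the planted observed/expected truth).

Event times are exponential with a constant per-person hazard, censored at
a fixed horizon — matching the Poisson person-time analysis model, so that
parameter recovery is directly interpretable.  Ages are drawn from a
normal per condition profile, truncated to [18, 100] and rounded to
integer years.  Multimorbidity counts are Poisson with mean linear in
(age - 50)/10 (floored at zero), which plants the age-multimorbidity
confounding that the dual standardization must disentangle.  Each
generated trial targets a single index condition, while cohort members may
hold several condition flags.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from saeratio.comorbidity import DEFAULT_CATEGORIES
from saeratio.ipd_pipeline import TrialIPD
from saeratio.trial_reconstruction import ArmRow, TrialSummary

DAYS_PER_YEAR = 365.25

#: Index condition -> comorbidity category it occupies (excluded from the
#: multimorbidity count of people for whom it is the index condition).
CONDITION_CATEGORY: dict[str, str] = {
    "copd": "asthma_copd",
    "asthma": "asthma_copd",
    "type_2_diabetes": "diabetes_mellitus",
    "hypertension": "cardiovascular_disease",
    "dementia": "dementia",
    "osteoarthritis": "arthritis",
    "osteoporosis": "osteoporosis",
    "epilepsy": "epilepsy",
    "parkinsons_disease": "parkinsonism",
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


class EmptySelectionError(RuntimeError):
    """Selection model excludes every candidate participant."""


@dataclass(frozen=True)
class ConditionProfile:
    """Age and multimorbidity profile of one index condition.

    ``prevalence`` is the fraction of the cohort holding the condition as
    their primary (index) condition; ``mm_mean_at_50``/``mm_slope_per_decade``
    parameterize the Poisson multimorbidity mean
    max(0, mm_mean_at_50 + mm_slope_per_decade * (age - 50)/10).
    """

    name: str
    prevalence: float
    age_mean: float
    age_sd: float
    mm_mean_at_50: float = 1.5
    mm_slope_per_decade: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.prevalence <= 1:
            raise ConfigError(f"{self.name}: prevalence must lie in (0, 1]")
        if self.age_sd <= 0:
            raise ConfigError(f"{self.name}: age_sd must be positive")


#: Default condition profiles: ages mirror large routine-care condition
#: registers (e.g. COPD mean 69.1 y, SD 11.6; type 2 diabetes 65.3/13.0),
#: prevalences their share of a ~2.3M population sample.
DEFAULT_PROFILES: tuple[ConditionProfile, ...] = (
    ConditionProfile("copd", 0.025, 69.1, 11.6, mm_mean_at_50=2.0),
    ConditionProfile("type_2_diabetes", 0.036, 65.3, 13.0, mm_mean_at_50=2.0),
    ConditionProfile("hypertension", 0.135, 67.0, 12.9, mm_mean_at_50=1.5),
    ConditionProfile("asthma", 0.083, 45.6, 22.9, mm_mean_at_50=1.2),
    ConditionProfile("osteoarthritis", 0.054, 67.6, 12.7, mm_mean_at_50=1.8),
    ConditionProfile("dementia", 0.006, 82.1, 9.0, mm_mean_at_50=2.5),
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic routine-care cohort.

    The SAE hazard per person-day is
    ``baseline_rate/365.25 * exp(b_age*(age-ref)/10 + b_sex*female + b_mm*mm)``
    with ``baseline_rate`` in events per person-year for a male of
    ``reference_age`` with zero comorbidities.
    """

    n_persons: int = 100_000
    condition_profiles: tuple[ConditionProfile, ...] = DEFAULT_PROFILES
    baseline_rate: float = 0.20
    reference_age: float = 70.0
    age_log_rr_per_decade: float = 0.40
    sex_log_rr: float = -0.10
    mm_log_rr_per_condition: float = 0.20
    percent_female: float = 52.0
    observation_days: float = 182.0
    condition_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ConfigError("n_persons must be positive")
        if self.observation_days <= 0:
            raise ConfigError("observation_days must be positive")
        if self.baseline_rate < 0:
            raise ConfigError("baseline_rate must be nonnegative")
        total = sum(p.prevalence for p in self.condition_profiles)
        if total > 1.0 + 1e-9:
            raise ConfigError("primary-condition prevalences sum above 1")
        if not 0 <= self.percent_female <= 100:
            raise ConfigError("percent_female out of [0, 100]")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SelectionModel:
    """Trial-selection mechanism with a planted hazard multiplier.

    Inclusion requires age in [age_lower, age_upper]; among eligible
    people the inclusion odds are scaled by exp(mm_penalty * mm_count), so
    negative ``mm_penalty`` under-samples multimorbid people.
    ``rate_multiplier`` (theta) scales the SAE hazard of enrolled
    participants and is the ground-truth observed/expected ratio.
    """

    age_lower: float = 18.0
    age_upper: float = 200.0
    mm_penalty: float = 0.0
    rate_multiplier: float = 1.0
    label: str = "null-selection"

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0:
            raise ConfigError("rate_multiplier must be positive")
        if self.age_lower > self.age_upper:
            raise ConfigError("age_lower must not exceed age_upper")


@dataclass
class Cohort:
    """Synthetic routine-care cohort.

    ``df`` has one row per person: person_id, age, sex, one ``cond_<name>``
    flag per condition, one ``cat_<name>`` medication-category flag per
    comorbidity category, mm_count, time_at_risk (days), event (0/1),
    event_day (NaN when censored) and the simulation-truth column
    true_hazard_per_day (never used by the analysis).
    """

    df: pd.DataFrame
    config: CohortConfig

    @property
    def observation_days(self) -> float:
        return self.config.observation_days

    @property
    def conditions(self) -> list[str]:
        return [p.name for p in self.config.condition_profiles]

    def condition_frame(self, condition: str) -> pd.DataFrame:
        col = f"cond_{condition}"
        if col not in self.df.columns:
            raise KeyError(f"unknown condition {condition!r}")
        return self.df[self.df[col]]


def _truncated_normal_ages(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    ages = rng.normal(mean, sd, size=size)
    bad = (ages < 18) | (ages > 100)
    while bad.any():
        ages[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (ages < 18) | (ages > 100)
    return np.floor(ages).astype(int).clip(18, 99)


def _hazard_per_day(config: CohortConfig, age, female, mm) -> np.ndarray:
    lp = (
        config.age_log_rr_per_decade * (np.asarray(age, float) - config.reference_age)
        / 10.0
        + config.sex_log_rr * np.asarray(female, float)
        + config.mm_log_rr_per_condition * np.asarray(mm, float)
    )
    return config.baseline_rate / DAYS_PER_YEAR * np.exp(lp)


def _simulate_first_event(
    rng: np.random.Generator, hazard_per_day: np.ndarray, horizon_days: float
):
    """Exponential first-event times censored at the horizon."""
    n = len(hazard_per_day)
    t = np.full(n, np.inf)
    pos = hazard_per_day > 0
    t[pos] = rng.exponential(1.0 / hazard_per_day[pos])
    event = (t <= horizon_days).astype(int)
    time_at_risk = np.minimum(t, horizon_days)
    event_day = np.where(event == 1, t, np.nan)
    return event, time_at_risk, event_day


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a synthetic routine-care cohort; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    profiles = config.condition_profiles

    # primary condition by prevalence; remaining mass -> background (no index
    # condition, mid-adult age profile)
    probs = np.array([p.prevalence for p in profiles])
    background = 1.0 - probs.sum()
    full = np.append(probs, max(background, 0.0))
    full = full / full.sum()
    primary = rng.choice(len(full), size=n, p=full)

    ages = np.empty(n, dtype=int)
    for k, prof in enumerate(profiles):
        mask = primary == k
        ages[mask] = _truncated_normal_ages(
            rng, prof.age_mean, prof.age_sd, int(mask.sum())
        )
    mask = primary == len(profiles)
    if mask.any():
        ages[mask] = _truncated_normal_ages(rng, 52.0, 18.0, int(mask.sum()))

    female = rng.random(n) < config.percent_female / 100.0

    # condition flags: primary condition always; secondary flags with an
    # age-affinity-weighted probability, so flag-holders have ages plausible
    # for the condition
    cond_flags = {}
    for k, prof in enumerate(profiles):
        flag = primary == k
        if config.condition_overlap > 0:
            affinity = np.exp(-0.5 * ((ages - prof.age_mean) / prof.age_sd) ** 2)
            p_sec = config.condition_overlap * prof.prevalence * affinity
            flag = flag | (rng.random(n) < p_sec)
        cond_flags[f"cond_{prof.name}"] = flag

    # multimorbidity: Poisson with mean linear in (age-50)/10, floored at 0
    mm_mean = np.zeros(n)
    for k, prof in enumerate(profiles):
        mask = primary == k
        mm_mean[mask] = np.maximum(
            0.0,
            prof.mm_mean_at_50
            + prof.mm_slope_per_decade * (ages[mask] - 50.0) / 10.0,
        )
    mask = primary == len(profiles)
    if mask.any():
        mm_mean[mask] = np.maximum(0.0, 1.0 + 0.4 * (ages[mask] - 50.0) / 10.0)
    n_cats = len(DEFAULT_CATEGORIES) - 1  # the index category never counts
    mm = np.minimum(rng.poisson(mm_mean), n_cats)

    # medication-category flags: mm distinct categories drawn uniformly from
    # the categories other than the person's index-condition category
    cat_names = list(DEFAULT_CATEGORIES)
    own_cat_idx = np.full(n, -1)
    for k, prof in enumerate(profiles):
        cat = CONDITION_CATEGORY.get(prof.name)
        if cat is not None:
            own_cat_idx[primary == k] = cat_names.index(cat)
    u = rng.random((n, len(cat_names)))
    u[own_cat_idx >= 0, own_cat_idx[own_cat_idx >= 0]] = np.inf  # never chosen
    order = np.argsort(u, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(len(cat_names))[None, :], axis=1)
    cat_matrix = ranks < mm[:, None]

    hazard = _hazard_per_day(config, ages, female, mm)
    event, time_at_risk, event_day = _simulate_first_event(
        rng, hazard, config.observation_days
    )

    df = pd.DataFrame(
        {
            "person_id": [f"p{i:07d}" for i in range(n)],
            "age": ages,
            "sex": np.where(female, "female", "male"),
            "mm_count": mm,
            "time_at_risk": time_at_risk,
            "event": event,
            "event_day": event_day,
            "true_hazard_per_day": hazard,
        }
    )
    for name, flag in cond_flags.items():
        df[name] = flag
    for j, cat in enumerate(cat_names):
        df[f"cat_{cat}"] = cat_matrix[:, j]
    return Cohort(df=df, config=config)


def generate_trial_suite(
    cohort: Cohort,
    condition: str,
    selection: SelectionModel,
    n_trials: int,
    n_per_trial: int,
    followup_days: float = 182.0,
    seed: int = 0,
    *,
    treatment_rate_multiplier: float = 1.0,
    id_prefix: str = "trial",
) -> tuple[list[TrialSummary], list[TrialIPD]]:
    """Sample trials from the cohort and re-simulate SAEs over the follow-up.

    Participants are drawn without replacement (independently per trial)
    with inclusion probability from ``selection``; their first-SAE times are
    re-simulated over ``followup_days`` with hazard scaled by the planted
    ``rate_multiplier`` (and by ``treatment_rate_multiplier`` in the
    treatment arm).  Aggregate summaries are tallied from the sampled IPD,
    so reconstruction can be validated against the truth.
    """
    rng = np.random.default_rng(seed)
    pool = cohort.condition_frame(condition)
    if len(pool) == 0:
        raise EmptySelectionError(f"cohort holds no one with condition {condition!r}")

    ages = pool["age"].to_numpy()
    eligible = (ages >= selection.age_lower) & (ages <= selection.age_upper)
    if not eligible.any():
        raise EmptySelectionError(
            f"selection {selection.label!r} excludes everyone: age bounds "
            f"[{selection.age_lower}, {selection.age_upper}] empty for "
            f"{condition!r}"
        )
    pool = pool[eligible]
    if len(pool) < n_per_trial:
        raise EmptySelectionError(
            f"only {len(pool)} eligible people for {condition!r}; "
            f"cannot sample {n_per_trial} per trial"
        )
    mm = pool["mm_count"].to_numpy(dtype=float)
    weights = expit(selection.mm_penalty * mm)

    base_hazard = pool["true_hazard_per_day"].to_numpy()
    ages = pool["age"].to_numpy()
    female = (pool["sex"] == "female").to_numpy()

    summaries: list[TrialSummary] = []
    ipds: list[TrialIPD] = []
    for t_idx in range(n_trials):
        # weighted sampling without replacement via the exponential race
        keys = rng.exponential(size=len(pool)) / weights
        take = np.argpartition(keys, n_per_trial - 1)[:n_per_trial]

        arm = np.where(rng.random(n_per_trial) < 0.5, "treatment", "control")
        mult = selection.rate_multiplier * np.where(
            arm == "treatment", treatment_rate_multiplier, 1.0
        )
        hazard = base_hazard[take] * mult
        event, time_at_risk, _ = _simulate_first_event(rng, hazard, followup_days)

        trial_id = f"{id_prefix}{t_idx:03d}"
        ipd_df = pd.DataFrame(
            {
                "participant_id": [f"{trial_id}_s{j:05d}" for j in range(n_per_trial)],
                "age": ages[take],
                "sex": np.where(female[take], "female", "male"),
                "arm": arm,
                "mm_count": mm[take].astype(int),
                "followup_days": time_at_risk,
                "sae": event,
            }
        )
        ipds.append(TrialIPD(trial_id=trial_id, condition=condition, df=ipd_df))

        arms = tuple(
            ArmRow(
                label=a,
                designation="experimental" if a == "treatment" else "placebo",
                n=int((arm == a).sum()),
                sae_count=int(event[arm == a].sum()),
            )
            for a in ("treatment", "control")
            if (arm == a).any()
        )
        # registries summarise continuous age; recorded integer age a stands
        # for the band [a, a+1), so summary moments use the band midpoint
        a_take = ages[take] + 0.5
        sd = float(a_take.std(ddof=1)) if n_per_trial > 1 else 0.0
        summaries.append(
            TrialSummary(
                trial_id=trial_id,
                condition=condition,
                n_participants=n_per_trial,
                age_mean=float(a_take.mean()),
                age_sd=sd if sd > 0 else None,
                age_min=float(a_take.min()),
                age_max=float(a_take.max()),
                percent_female=float(100.0 * female[take].mean()),
                followup_days=float(followup_days),
                sae_count=int(event.sum()),
                arms=arms,
            )
        )
    return summaries, ipds
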