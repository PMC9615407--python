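"""Individual-participant-data (IPD) analyses.

Three analyses run on per-participant trial data: (i) the association
between multimorbidity count and first SAE per sex, estimated by Poisson
regression with a linear age adjustment and log time-to-event/censoring
offset, pooled across trials by REML meta-analysis and restricted to
sex strata with at least 20 SAEs; (ii) treatment-arm main effects per sex
and the arm-by-multimorbidity interaction, meta-analysed the same way; and
(iii) the paired standardization comparing each trial's observed/expected
ratio on an age/sex basis against an age/sex/multimorbidity basis fitted
on the same cohort — the decomposition showing how much of a trial's
SAE deficit is explained by its lower multimorbidity.

Associations use the first-SAE (0/1) framing consistent with the cohort's
first-event definition; observed counts for O/E ratios are the trials'
total SAE participant counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from saeratio.expectation import expected_events_ipd
from saeratio.oe_inference import MetaResult, OERatioEstimate, meta_analyze, oe_ratio
from saeratio.rate_models import RateModel

logger = logging.getLogger(__name__)

#: Minimum SAEs per sex stratum for the association analysis.
MIN_EVENTS_PER_SEX = 20


@dataclass
class TrialIPD:
    """Per-participant records for one trial.

    ``df`` columns: participant_id, age, sex, arm (treatment | control),
    mm_count (or a ``medications`` token column from which it is derived),
    followup_days (time to first SAE or end of follow-up) and sae (0/1).
    """

    trial_id: str
    condition: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "followup_days" in self.df.columns and (
            self.df["followup_days"] <= 0
        ).any():
            raise ValueError(
                f"trial {self.trial_id}: followup_days must be positive"
            )

    @property
    def observed_sae(self) -> int:
        return int(self.df["sae"].sum())


@dataclass
class MMAssociation:
    """Multimorbidity-SAE association in one trial/sex stratum."""

    trial_id: str
    sex: str
    coef: float
    se: float
    n_events: int


@dataclass
class DualStandardization:
    """Paired age/sex vs age/sex/multimorbidity O/E ratios for one trial."""

    trial_id: str
    ratio_age_sex: OERatioEstimate
    ratio_age_sex_mm: OERatioEstimate

    @property
    def shift(self) -> float:
        return self.ratio_age_sex_mm.ratio - self.ratio_age_sex.ratio


@dataclass
class InteractionResult:
    """Pooled arm main effects per sex and the arm x multimorbidity interaction."""

    interaction: MetaResult
    arm_effect_by_sex: dict[str, MetaResult]
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _fit_poisson(y, X, offset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise np.linalg.LinAlgError("nonfinite Poisson fit")
    return res


def mm_sae_association(trial: TrialIPD, sex: str) -> MMAssociation | None:
    """Multimorbidity coefficient for one trial/sex stratum, or None.

    Fits first-SAE ~ multimorbidity count + age (linear) with a log
    time-at-risk offset.  Strata with fewer than 20 SAEs, constant
    multimorbidity, or an inestimable fit are excluded with a logged
    reason and return None.
    """
    df = trial.df[trial.df["sex"] == sex]
    n_events = int(df["sae"].sum()) if len(df) else 0
    if n_events < MIN_EVENTS_PER_SEX:
        logger.info(
            "trial %s %s stratum excluded: %d SAEs (< %d)",
            trial.trial_id, sex, n_events, MIN_EVENTS_PER_SEX,
        )
        return None
    mm = df["mm_count"].to_numpy(dtype=float)
    if np.ptp(mm) == 0:
        logger.info(
            "trial %s %s stratum skipped: multimorbidity count constant (%g)",
            trial.trial_id, sex, mm[0],
        )
        return None
    X = np.column_stack(
        [np.ones(len(df)), mm, df["age"].to_numpy(dtype=float)]
    )
    offset = np.log(df["followup_days"].to_numpy(dtype=float))
    try:
        res = _fit_poisson(df["sae"].to_numpy(dtype=float), X, offset)
    except np.linalg.LinAlgError as exc:
        logger.info("trial %s %s stratum skipped: %s", trial.trial_id, sex, exc)
        return None
    return MMAssociation(
        trial_id=trial.trial_id,
        sex=sex,
        coef=float(res.params[1]),
        se=float(res.bse[1]),
        n_events=n_events,
    )


def pooled_mm_association(
    trials: list[TrialIPD], sex: str
) -> tuple[MetaResult | None, list[MMAssociation]]:
    """REML-pooled multimorbidity coefficient across trials for one sex."""
    assocs = [a for t in trials if (a := mm_sae_association(t, sex)) is not None]
    if not assocs:
        return None, []
    pooled = meta_analyze([(a.coef, a.se) for a in assocs])
    return pooled, assocs


def rate_ratio_curve(
    pooled_coef: float,
    pooled_se: float,
    mm_values: np.ndarray | list[int],
) -> pd.DataFrame:
    """Rate-ratio curve RR(mm) = exp(coef * mm) with a 95% band.

    The reference is mm = 0 (RR exactly 1 there); the band propagates the
    pooled coefficient SE by the delta method on the log scale, and the
    curve should only be evaluated over the multimorbidity range observed
    in the trials.
    """
    mm = np.asarray(mm_values, dtype=float)
    log_rr = pooled_coef * mm
    half = 1.959963984540054 * pooled_se * np.abs(mm)
    return pd.DataFrame(
        {
            "mm_count": mm,
            "rate_ratio": np.exp(log_rr),
            "lower": np.exp(log_rr - half),
            "upper": np.exp(log_rr + half),
        }
    )


def mm_treatment_interaction(trials: list[TrialIPD]) -> InteractionResult:
    """Arm main effects (per sex) and the arm x multimorbidity interaction.

    Per trial, fits first-SAE ~ arm + mm + arm:mm + age with log
    time-at-risk offset (both sexes combined, sex-adjusted); interaction
    coefficients are REML meta-analysed.  Arm main effects are estimated
    per sex from sex-stratified fits of SAE ~ arm + mm + age.  Single-arm
    trials and inestimable fits are skipped with a reason.
    """
    inter_effects: list[tuple[float, float]] = []
    arm_effects: dict[str, list[tuple[float, float]]] = {"male": [], "female": []}
    skipped: list[tuple[str, str]] = []

    for trial in trials:
        df = trial.df
        arms = df["arm"].unique()
        if len(arms) < 2:
            skipped.append((trial.trial_id, "single-arm trial"))
            continue
        treat = (df["arm"] == "treatment").to_numpy(dtype=float)
        mm = df["mm_count"].to_numpy(dtype=float)
        age = df["age"].to_numpy(dtype=float)
        female = (df["sex"] == "female").to_numpy(dtype=float)
        y = df["sae"].to_numpy(dtype=float)
        offset = np.log(df["followup_days"].to_numpy(dtype=float))
        X = np.column_stack(
            [np.ones(len(df)), treat, mm, treat * mm, age, female]
        )
        try:
            res = _fit_poisson(y, X, offset)
            inter_effects.append((float(res.params[3]), float(res.bse[3])))
        except np.linalg.LinAlgError as exc:
            skipped.append((trial.trial_id, f"interaction fit: {exc}"))

        for sex in ("male", "female"):
            sub = df[df["sex"] == sex]
            if len(sub) < 10 or sub["sae"].sum() == 0:
                skipped.append((trial.trial_id, f"{sex}: too few events"))
                continue
            Xs = np.column_stack(
                [
                    np.ones(len(sub)),
                    (sub["arm"] == "treatment").to_numpy(dtype=float),
                    sub["mm_count"].to_numpy(dtype=float),
                    sub["age"].to_numpy(dtype=float),
                ]
            )
            try:
                r = _fit_poisson(
                    sub["sae"].to_numpy(dtype=float),
                    Xs,
                    np.log(sub["followup_days"].to_numpy(dtype=float)),
                )
                arm_effects[sex].append((float(r.params[1]), float(r.bse[1])))
            except np.linalg.LinAlgError as exc:
                skipped.append((trial.trial_id, f"{sex} arm fit: {exc}"))

    if not inter_effects:
        raise ValueError("no trial yielded an estimable interaction")
    return InteractionResult(
        interaction=meta_analyze(inter_effects),
        arm_effect_by_sex={
            sex: meta_analyze(effs) for sex, effs in arm_effects.items() if effs
        },
        skipped=skipped,
    )


def dual_standardization(
    trial: TrialIPD,
    models_age_sex: dict[str, RateModel],
    models_age_sex_mm: dict[str, RateModel],
    *,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> DualStandardization:
    """Paired O/E ratios on the age/sex and age/sex/multimorbidity bases.

    Both expected counts come from the same cohort via
    :func:`saeratio.expectation.expected_events_ipd`; the pair quantifies
    how much of the trial's SAE deficit the multimorbidity difference
    explains.
    """
    obs = trial.observed_sae
    e_as = expected_events_ipd(
        models_age_sex, trial, basis="age_sex", n_draws=n_draws, seed=seed
    )
    e_mm = expected_events_ipd(
        models_age_sex_mm, trial, basis="age_sex_mm", n_draws=n_draws,
        seed=None if seed is None else seed + 1,
    )
    r_as = oe_ratio(obs, e_as, n_draws=n_draws, seed=seed)
    r_mm = oe_ratio(
        obs, e_mm, n_draws=n_draws, seed=None if seed is None else seed + 1
    )
    return DualStandardization(
        trial_id=trial.trial_id, ratio_age_sex=r_as, ratio_age_sex_mm=r_mm
    )
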