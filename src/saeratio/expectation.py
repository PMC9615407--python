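"""Expected SAE counts by indirect standardization against cohort rate models.

For aggregate trials the expected count sums, over sex and one-year age
band, the model rate at the mid-band age times the person-time apportioned
to that cell; total trial person-time uses the incident-event-corrected
formula ``followup x N - 0.5 x followup x events``.  For IPD trials each
participant contributes their own exposure days at their exact age, sex
(and optionally multimorbidity count), so no half-event correction is
needed.  Coefficient-sampled draws of the expected count propagate
rate-model uncertainty into downstream interval estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from saeratio.rate_models import RateModel, RateModelError
from saeratio.trial_reconstruction import AgeSexDistribution

logger = logging.getLogger(__name__)


@dataclass
class ExpectedCount:
    """Expected SAE count for one trial under one standardization basis."""

    trial_id: str
    expected: float
    basis: str  # age_sex | age_sex_mm
    person_time_days: float
    draws: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expected < 0:
            raise ValueError("expected count must be nonnegative")
        if self.basis not in {"age_sex", "age_sex_mm"}:
            raise ValueError(f"unknown basis {self.basis!r}")


def aggregate_person_time(n: int, followup_days: float, events: int) -> float:
    """Approximate person-days for an aggregate trial.

    ``followup x n - 0.5 x followup x events``: each incident event is
    assumed to occur midway through follow-up.  When events exceed n the
    result is floored at half the nominal person-time (every participant
    contributing half their follow-up) with a warning.
    """
    if n <= 0 or followup_days <= 0 or events < 0:
        raise ValueError("need n > 0, followup_days > 0, events >= 0")
    pt = followup_days * n - 0.5 * followup_days * events
    floor = 0.5 * followup_days * n
    if events > n:
        logger.warning(
            "events (%d) exceed participants (%d); person-time floored at "
            "half the nominal total",
            events,
            n,
        )
        return floor
    return pt


def expected_events_aggregate(
    models: dict[str, RateModel],
    dist: AgeSexDistribution,
    n: int,
    followup_days: float,
    events: int,
    *,
    trial_id: str = "",
    n_draws: int = 0,
    seed: int | None = None,
    coef_draws: dict[str, np.ndarray] | None = None,
) -> ExpectedCount:
    """Expected SAEs for an aggregate trial from reconstructed age bands.

    ``expected = sum_sex sum_band rate(band, sex) * PT_cell`` with band
    rates at the band midpoint.  Cell person-time is the headcount share
    ``w_band * p_sex * followup * n`` minus the event-related deficit
    (``0.5 * followup`` per event, from :func:`aggregate_person_time`)
    apportioned across cells by their expected event share — events'
    locations are unreported, and they concentrate where rates are high.
    With ``n_draws`` > 0 the computation is repeated with
    multivariate-normal coefficient samples per sex model; passing
    ``coef_draws`` (sex -> (S, p) coefficient samples) shares one set of
    samples across several trials so their expected-count uncertainties
    correlate through the common rate models.
    """
    pt_total = aggregate_person_time(n, followup_days, events)
    pt_deficit = followup_days * n - pt_total  # person-time lost to events
    rng = np.random.default_rng(seed)
    if coef_draws is not None:
        n_draws = len(next(iter(coef_draws.values())))

    cells = []
    for sex, prop in dist.sex_proportions.items():
        if prop <= 0:
            continue
        if sex not in models:
            raise RateModelError(
                f"no rate model for sex {sex!r} but the trial has "
                f"{100 * prop:.1f}% of participants of that sex"
            )
        model = models[sex]
        w = dist.weights[sex]
        # band labels are recorded integer ages; the model's age spec maps
        # them to band midpoints internally
        band_ages = w.index.values.astype(float)
        if n_draws > 0:
            point, draws = model.predict_rate(
                band_ages, n_draws=n_draws, rng=rng,
                coef_draws=None if coef_draws is None else coef_draws[sex],
            )
        else:
            point = model.predict_rate(band_ages)
            draws = None
        cells.append((prop * w.values, point, draws))

    # headcount person-time per cell, minus the event deficit apportioned by
    # expected event share (events concentrate where rates are high; their
    # band locations are unknown, so the model's own rates estimate them)
    event_share_denom = sum(float(wp @ r) for wp, r, _ in cells)
    expected = 0.0
    draw_total = np.zeros(n_draws) if n_draws > 0 else None
    for wp, point, draws in cells:
        cell_pt = followup_days * n * wp
        if event_share_denom > 0:
            cell_pt = cell_pt - pt_deficit * (wp * point) / event_share_denom
        expected += float(point @ cell_pt)
        if draws is not None:
            draw_total += draws @ cell_pt

    return ExpectedCount(
        trial_id=trial_id,
        expected=expected,
        basis="age_sex",
        person_time_days=pt_total,
        draws=draw_total,
        meta={
            "fallback_uniform": dist.fallback_uniform,
            "sd_imputed": dist.sd_imputed,
            "models": {s: m.condition for s, m in models.items()},
        },
    )


def expected_events_ipd(
    models: dict[str, RateModel],
    ipd,
    basis: str = "age_sex",
    *,
    n_draws: int = 0,
    seed: int | None = None,
) -> ExpectedCount:
    """Expected SAEs for an IPD trial from observed participant profiles.

    Each participant contributes ``rate(age, sex[, mm]) x followup_days``;
    exposure is exact, so no half-event correction applies.
    """
    if basis not in {"age_sex", "age_sex_mm"}:
        raise ValueError(f"unknown basis {basis!r}")
    df = ipd.df
    if (df["followup_days"] <= 0).any():
        raise ValueError(f"trial {ipd.trial_id}: nonpositive follow-up days")
    use_mm = basis == "age_sex_mm"
    if use_mm and "mm_count" not in df.columns:
        raise RateModelError(
            f"trial {ipd.trial_id}: basis age_sex_mm needs mm_count per participant"
        )

    rng = np.random.default_rng(seed)
    expected = 0.0
    draw_total = np.zeros(n_draws) if n_draws > 0 else None
    for sex, grp in df.groupby("sex", sort=True):
        if sex not in models:
            raise RateModelError(f"no rate model for sex {sex!r}")
        model = models[sex]
        if use_mm and not model.has_mm:
            raise RateModelError(
                f"basis age_sex_mm requested but the {sex} model has no "
                "multimorbidity term"
            )
        ages = grp["age"].to_numpy(dtype=float)
        t = grp["followup_days"].to_numpy(dtype=float)
        mm = grp["mm_count"].to_numpy(dtype=float) if use_mm else None
        if n_draws > 0:
            point, draws = model.predict_rate(ages, mm, n_draws=n_draws, rng=rng)
            draw_total += draws @ t
        else:
            point = model.predict_rate(ages, mm)
        expected += float(point @ t)

    return ExpectedCount(
        trial_id=ipd.trial_id,
        expected=expected,
        basis=basis,
        person_time_days=float(df["followup_days"].sum()),
        draws=draw_total,
        meta={"n_participants": int(len(df))},
    )
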