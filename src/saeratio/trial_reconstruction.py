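"""Reconstruct per-sex one-year age-band weights from trial summary statistics.

Trial registries report age only as summary statistics (mean, SD, minimum,
maximum) plus the percentage of female participants.  Indirect
standardization, however, needs the share of participants in each one-year
age band.  We recover those shares by fitting a truncated normal
distribution on [age_min, age_max] whose *truncated* mean and SD match the
reported moments, then integrating it over integer-year bands.  The same
age distribution is applied to both sexes (registries rarely stratify age
summaries by sex), split by the reported percent female.

When the reported SD is too large to be attainable by any truncated normal
on the reported range (the supremum is the uniform SD, (max-min)/sqrt(12)),
the maximum-entropy fallback — uniform on [min, max] — is used and flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArmRow:
    """SAE results for one arm of a trial."""

    label: str
    designation: str  # experimental | active | placebo
    n: int
    sae_count: int

    def __post_init__(self) -> None:
        if self.designation not in {"experimental", "active", "placebo"}:
            raise ValueError(f"unknown arm designation {self.designation!r}")
        if self.n <= 0 or self.sae_count < 0:
            raise ValueError("arm n must be positive and sae_count nonnegative")


@dataclass(frozen=True)
class TrialSummary:
    """Registry-style aggregate record for one trial.

    ``sae_count`` may exceed ``n_participants`` (a participant can have more
    than one SAE); it only needs to be nonnegative.
    """

    trial_id: str
    condition: str
    n_participants: int
    age_mean: float
    age_min: float
    age_max: float
    percent_female: float
    followup_days: float
    sae_count: int
    age_sd: float | None = None
    arms: tuple[ArmRow, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.age_min <= self.age_mean <= self.age_max):
            raise ValueError(
                f"trial {self.trial_id}: need age_min <= age_mean <= age_max, "
                f"got {self.age_min}, {self.age_mean}, {self.age_max}"
            )
        if not (0.0 <= self.percent_female <= 100.0):
            raise ValueError(f"trial {self.trial_id}: percent_female out of [0, 100]")
        if self.n_participants <= 0:
            raise ValueError(f"trial {self.trial_id}: n_participants must be positive")
        if self.sae_count < 0:
            raise ValueError(f"trial {self.trial_id}: sae_count must be nonnegative")
        if self.followup_days <= 0:
            raise ValueError(f"trial {self.trial_id}: followup_days must be positive")
        if self.age_sd is not None and self.age_sd <= 0:
            raise ValueError(f"trial {self.trial_id}: age_sd must be positive")


@dataclass(frozen=True)
class AgeSexDistribution:
    """Per-sex weights over integer one-year age bands [a, a+1).

    ``weights`` maps sex -> Series indexed by band lower edge; each sex's
    weights sum to one.  ``sex_proportions`` gives the share of the trial in
    each sex and sums to one.
    """

    weights: dict[str, pd.Series]
    sex_proportions: dict[str, float]
    fallback_uniform: bool = False
    sd_imputed: bool = False

    def __post_init__(self) -> None:
        for sex, w in self.weights.items():
            if (w < 0).any():
                raise ValueError(f"negative band weight for sex {sex}")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"band weights for sex {sex} do not sum to 1")
        if abs(sum(self.sex_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("sex proportions do not sum to 1")

    def mean_age(self) -> float:
        """Mean of the discrete distribution using mid-band ages."""
        total = 0.0
        for sex, w in self.weights.items():
            p = self.sex_proportions[sex]
            total += p * float(((w.index.values + 0.5) * w.values).sum())
        return total


def _truncnorm_moments(mu: float, sigma: float, lower: float, upper: float):
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def truncated_normal_from_moments(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float, bool]:
    """Parent-normal (mu, sigma) whose truncation to [lower, upper] has the
    given mean and SD.

    Returns ``(mu, sigma, fallback)``.  Solved numerically to |dmean| and
    |dsd| below 1e-6 years.  ``fallback=True`` signals that no truncated
    normal attains the requested SD on the interval (the supremum is the
    uniform SD) and the caller should use a uniform distribution instead;
    the returned (mu, sigma) are then the midpoint and a large sigma.
    """
    if not lower < upper:
        raise ValueError("need lower < upper")
    if not (lower <= mean <= upper):
        raise ValueError(f"mean {mean} outside bounds [{lower}, {upper}]")
    if sd <= 0:
        raise ValueError("sd must be positive")

    width = upper - lower
    uniform_sd = width / math.sqrt(12.0)
    if sd >= uniform_sd:
        logger.warning(
            "requested sd %.3f >= attainable supremum %.3f on [%g, %g]; "
            "uniform fallback",
            sd,
            uniform_sd,
            lower,
            upper,
        )
        return (lower + upper) / 2.0, 1e3 * width, True

    def resid(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        m, s = _truncnorm_moments(mu, sigma, lower, upper)
        return np.array([m - mean, s - sd])

    x0 = np.array([mean, math.log(sd)])
    sol = optimize.root(resid, x0, method="hybr", tol=1e-12)
    r = resid(sol.x)
    if not sol.success or np.max(np.abs(r)) > 1e-6:
        # retry from a midpoint-centred start before giving up
        sol = optimize.root(
            resid, np.array([(lower + upper) / 2.0, math.log(sd)]), method="hybr"
        )
        r = resid(sol.x)
        if np.max(np.abs(r)) > 1e-6:
            logger.warning(
                "truncated-normal moment match failed (residual %.2e); "
                "uniform fallback",
                float(np.max(np.abs(r))),
            )
            return (lower + upper) / 2.0, 1e3 * width, True
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    return mu, sigma, False


def reconstruct_age_distribution(summary: TrialSummary) -> AgeSexDistribution:
    """One-year age-band weights per sex for an aggregate trial.

    Band weight is the fitted truncated-normal probability mass on
    [a, a+1), renormalized over [floor(age_min), ceil(age_max)).  A missing
    age SD is imputed as (age_max - age_min)/4 and flagged.  Degenerate
    bounds (age_min == age_max) give a point mass at that band.
    """
    p_f = summary.percent_female / 100.0
    sex_props = {"female": p_f, "male": 1.0 - p_f}

    lo_band = int(math.floor(summary.age_min))
    hi_band = int(math.ceil(summary.age_max))

    if summary.age_min == summary.age_max:
        bands = np.array([lo_band])
        w = pd.Series([1.0], index=bands)
        return AgeSexDistribution(
            weights={"male": w, "female": w.copy()},
            sex_proportions=sex_props,
        )

    sd_imputed = summary.age_sd is None
    sd = summary.age_sd if summary.age_sd is not None else (
        (summary.age_max - summary.age_min) / 4.0
    )
    if sd_imputed:
        logger.warning(
            "trial %s: age SD missing; imputed (max-min)/4 = %.2f",
            summary.trial_id,
            sd,
        )

    mu, sigma, fallback = truncated_normal_from_moments(
        summary.age_mean, sd, summary.age_min, summary.age_max
    )

    edges = np.arange(lo_band, hi_band + 1, dtype=float)
    edges_clipped = np.clip(edges, summary.age_min, summary.age_max)
    if fallback:
        cdf = (edges_clipped - summary.age_min) / (summary.age_max - summary.age_min)
    else:
        a, b = (summary.age_min - mu) / sigma, (summary.age_max - mu) / sigma
        cdf = stats.truncnorm.cdf(edges_clipped, a, b, loc=mu, scale=sigma)
    mass = np.diff(cdf)
    total = mass.sum()
    if total <= 0:
        raise RuntimeError(f"trial {summary.trial_id}: degenerate band mass")
    mass = mass / total
    bands = edges[:-1].astype(int)
    w = pd.Series(mass, index=bands)

    return AgeSexDistribution(
        weights={"male": w, "female": w.copy()},
        sex_proportions=sex_props,
        fallback_uniform=fallback,
        sd_imputed=sd_imputed,
    )


def distribution_table(
    dists: dict[str, AgeSexDistribution]
) -> pd.DataFrame:
    """Long-format band-weight table (trial_id, sex, age, weight)."""
    rows = []
    for tid, dist in dists.items():
        for sex, w in dist.weights.items():
            for age, weight in w.items():
                rows.append((tid, sex, int(age), float(weight)))
    return pd.DataFrame(rows, columns=["trial_id", "sex", "age", "weight"])
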