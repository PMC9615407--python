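"""Sex-stratified fractional-polynomial Poisson rate models.

First urgent hospitalisation or death in the routine-care cohort is
modelled as a Poisson count per person with the log of person-days at risk
as offset, stratified by sex and index condition.  Age (and optionally the
multimorbidity count) enters through fractional-polynomial (FP) bases with
powers from {-2, -1, -0.5, 0, 0.5, 1, 2, 3}: power 0 denotes log(x) and a
repeated power p contributes the pair (x^p, x^p log x).  Power selection is
an exhaustive deviance search over all FP1 and FP2 candidates with a
closed-test simplification (chi-square, 2 df per stage, alpha = 0.05): the
best FP2 is kept only if it beats the best FP1, which in turn is kept only
if it beats the linear model.

Age is divided by 10 before transformation (strictly positive for adult
cohorts); multimorbidity counts are shifted by +1 (zero is a valid count).
Fitted models expose point and coefficient-sampled rate predictions per
person-day and serialize to JSON so standardization can run without
refitting.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Conventional fractional-polynomial power set.
FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: Events below which power selection falls back to a linear term.
MIN_EVENTS_FOR_SELECTION = 50


class RateModelError(RuntimeError):
    """Raised for degenerate strata (no events, no exposure) or misuse."""


class FPDomainError(ValueError):
    """Raised when an FP transform argument is nonpositive."""


def fp_transform(x: np.ndarray | float, powers: tuple[float, ...]) -> np.ndarray:
    """Fractional-polynomial basis columns for positive ``x``.

    Power p gives x**p, p = 0 gives log(x), and each repetition of a power
    multiplies by a further log(x) factor (so powers (2, 2) give
    (x^2, x^2 log x)).  Returns an array of shape (n, len(powers)).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        shift = float(-x.min()) + 1e-6
        raise FPDomainError(
            f"FP transform needs strictly positive input; shift by at least "
            f"{shift:.6g} before transforming"
        )
    cols = []
    seen: dict[float, int] = {}
    logx = np.log(x)
    for p in powers:
        reps = seen.get(p, 0)
        base = logx if p == 0 else x**p
        cols.append(base * logx**reps)
        seen[p] = reps + 1
    return np.column_stack(cols)


@dataclass(frozen=True)
class FPSpec:
    """Fractional-polynomial specification for one covariate."""

    variable: str
    powers: tuple[float, ...]
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.powers) > 2:
            raise ValueError("at most two FP terms are supported")
        if tuple(sorted(self.powers)) != tuple(self.powers):
            raise ValueError("powers must be sorted")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def design(self, x: np.ndarray | float) -> np.ndarray:
        z = (np.atleast_1d(np.asarray(x, dtype=float)) + self.shift) / self.scale
        return fp_transform(z, self.powers)


def default_age_spec(powers: tuple[float, ...] = (1.0,)) -> FPSpec:
    # recorded integer age a denotes the band [a, a+1); the covariate is the
    # band midpoint a + 0.5, so band-weighted and per-person predictions agree
    return FPSpec(variable="age", powers=powers, shift=0.5, scale=10.0)


def default_mm_spec(powers: tuple[float, ...] = (1.0,)) -> FPSpec:
    return FPSpec(variable="mm_count", powers=powers, shift=1.0, scale=1.0)


def _poisson_deviance_fit(y, X, offset):
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def _candidate_power_sets(max_degree: int):
    cands = [(p,) for p in FP_POWERS]
    if max_degree >= 2:
        cands += list(itertools.combinations_with_replacement(FP_POWERS, 2))
    return cands


def select_fp_powers(
    data: pd.DataFrame,
    variable: str,
    *,
    events_col: str = "event",
    time_col: str = "time_at_risk",
    shift: float = 0.0,
    scale: float = 1.0,
    extra_design: np.ndarray | None = None,
    max_degree: int = 2,
    alpha: float = 0.05,
) -> FPSpec:
    """Select FP powers for ``variable`` by exhaustive deviance search.

    All FP1 and FP2 candidates are fitted (with intercept, optional extra
    design columns and log person-time offset); non-converging candidates
    are skipped and logged.  The deviance-minimizing FP2 is simplified by a
    closed chi-square test (2 df per stage at ``alpha``): FP2 -> best FP1
    -> linear.  Strata with fewer than 50 events fall back to a linear term
    with a warning.
    """
    from scipy import stats as sps

    y = data[events_col].to_numpy(dtype=float)
    t = data[time_col].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise RateModelError("nonpositive person-time in selection data")
    offset = np.log(t)
    n_events = float(y.sum())
    if n_events < MIN_EVENTS_FOR_SELECTION:
        logger.warning(
            "only %.0f events in stratum; falling back to linear %s term",
            n_events,
            variable,
        )
        return FPSpec(variable=variable, powers=(1.0,), shift=shift, scale=scale)

    z = (data[variable].to_numpy(dtype=float) + shift) / scale
    if np.any(z <= 0):
        raise FPDomainError(
            f"{variable}: transformed values must be positive; increase shift"
        )

    def fit_powers(powers: tuple[float, ...]):
        basis = fp_transform(z, powers)
        cols = [np.ones_like(z), basis]
        if extra_design is not None:
            cols.append(extra_design)
        X = np.column_stack(cols)
        try:
            res = _poisson_deviance_fit(y, X, offset)
        except Exception as exc:  # pragma: no cover - rare numeric failure
            logger.warning("FP candidate %s skipped: %s", powers, exc)
            return None
        if not np.all(np.isfinite(res.params)):
            logger.warning("FP candidate %s skipped: nonfinite fit", powers)
            return None
        return float(res.deviance)

    dev: dict[tuple[float, ...], float] = {}
    for powers in _candidate_power_sets(max_degree):
        d = fit_powers(powers)
        if d is not None:
            dev[powers] = d

    if (1.0,) not in dev:
        raise RateModelError("linear candidate failed to fit")
    dev_lin = dev[(1.0,)]
    fp1 = {p: d for p, d in dev.items() if len(p) == 1}
    best1 = min(fp1, key=fp1.get)
    chosen: tuple[float, ...] = (1.0,)
    if max_degree >= 2:
        fp2 = {p: d for p, d in dev.items() if len(p) == 2}
        if fp2:
            best2 = min(fp2, key=fp2.get)
            crit = sps.chi2.ppf(1 - alpha, df=2)
            if dev[best1] - dev[best2] > crit:
                chosen = best2
            elif dev_lin - dev[best1] > crit:
                chosen = best1
        elif dev_lin - dev[best1] > sps.chi2.ppf(1 - alpha, df=2):
            chosen = best1
    else:
        if dev_lin - dev[best1] > sps.chi2.ppf(1 - alpha, df=2):
            chosen = best1
    return FPSpec(
        variable=variable, powers=tuple(sorted(chosen)), shift=shift, scale=scale
    )


@dataclass
class RateModel:
    """Fitted Poisson rate model for one sex/condition stratum.

    Rates are per person-day.  ``params`` holds the intercept followed by
    one coefficient per FP column of each spec, in spec order; ``cov`` is
    the coefficient covariance used for sampling-based uncertainty.
    """

    sex: str
    condition: str
    specs: dict[str, FPSpec]
    params: np.ndarray
    cov: np.ndarray
    age_support: tuple[float, float]
    n_persons: int = 0
    n_events: int = 0
    time_unit: str = "person-days"
    meta: dict = field(default_factory=dict)

    @property
    def has_mm(self) -> bool:
        return "mm_count" in self.specs

    def _design(self, age, mm_count=None) -> np.ndarray:
        age = np.atleast_1d(np.asarray(age, dtype=float))
        lo, hi = self.age_support
        lo_c, hi_c = lo - 5.0, hi + 5.0
        if np.any(age < lo_c) or np.any(age > hi_c):
            logger.warning(
                "ages outside fitted support [%g, %g] +/- 5 y clamped", lo, hi
            )
        age = np.clip(age, lo_c, hi_c)
        cols = [np.ones_like(age), self.specs["age"].design(age)]
        if self.has_mm:
            if mm_count is None:
                raise RateModelError(
                    "model includes multimorbidity count; mm_count is required"
                )
            mm = np.broadcast_to(
                np.atleast_1d(np.asarray(mm_count, dtype=float)), age.shape
            )
            cols.append(self.specs["mm_count"].design(mm))
        elif mm_count is not None:
            raise RateModelError("mm_count supplied to an age-only model")
        return np.column_stack(cols)

    def predict_rate(
        self,
        age,
        mm_count=None,
        *,
        n_draws: int = 0,
        rng: np.random.Generator | None = None,
        coef_draws: np.ndarray | None = None,
    ):
        """Event rate per person-day at the given age (and mm count).

        With ``n_draws`` > 0, additionally returns an (n_draws, n) array of
        rates computed from multivariate-normal coefficient samples.
        Passing ``coef_draws`` (an (S, p) array of coefficient samples, e.g.
        from :meth:`coefficient_draws`) reuses those samples instead, which
        lets several predictions share one set of draws so that their
        uncertainties are correlated as the model's uncertainty really is.
        """
        X = self._design(age, mm_count)
        point = np.exp(X @ self.params)
        if coef_draws is None:
            if n_draws <= 0:
                return point
            if rng is None:
                rng = np.random.default_rng()
            coef_draws = rng.multivariate_normal(
                self.params, self.cov, size=n_draws, method="cholesky"
            )
        draws = np.exp(coef_draws @ X.T)
        return point, draws

    def coefficient_draws(
        self, n_draws: int, rng: np.random.Generator
    ) -> np.ndarray:
        return rng.multivariate_normal(self.params, self.cov, size=n_draws,
                                       method="cholesky")

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "condition": self.condition,
            "specs": {
                v: {
                    "powers": list(s.powers),
                    "shift": s.shift,
                    "scale": s.scale,
                }
                for v, s in self.specs.items()
            },
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "age_support": list(self.age_support),
            "n_persons": self.n_persons,
            "n_events": self.n_events,
            "time_unit": self.time_unit,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateModel":
        specs = {
            v: FPSpec(
                variable=v,
                powers=tuple(s["powers"]),
                shift=s["shift"],
                scale=s["scale"],
            )
            for v, s in d["specs"].items()
        }
        return cls(
            sex=d["sex"],
            condition=d["condition"],
            specs=specs,
            params=np.asarray(d["params"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            age_support=tuple(d["age_support"]),
            n_persons=d.get("n_persons", 0),
            n_events=d.get("n_events", 0),
            time_unit=d.get("time_unit", "person-days"),
            meta=d.get("meta", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RateModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_rate_model(
    cohort,
    condition: str,
    sex: str,
    covariates: set[str] | frozenset[str] = frozenset({"age"}),
    *,
    select_powers: bool = True,
    age_powers: tuple[float, ...] | None = None,
    mm_powers: tuple[float, ...] | None = None,
) -> RateModel:
    """Fit the sex-stratified Poisson rate model for one index condition.

    ``covariates`` is {"age"} or {"age", "mm_count"}.  Power selection runs
    per covariate (age first in an age-only model, then multimorbidity with
    the age basis held fixed) unless explicit powers are supplied or
    ``select_powers`` is False (then linear terms are used).
    """
    covariates = frozenset(covariates)
    if not covariates <= {"age", "mm_count"} or "age" not in covariates:
        raise ValueError("covariates must be {'age'} or {'age', 'mm_count'}")

    df = cohort.condition_frame(condition)
    df = df[df["sex"] == sex]
    if len(df) == 0:
        raise RateModelError(f"empty stratum: {condition}/{sex}")
    t = df["time_at_risk"].to_numpy(dtype=float)
    if not np.any(t > 0):
        raise RateModelError(f"no person-time at risk in stratum {condition}/{sex}")
    keep = t > 0
    df = df.loc[keep]
    t = t[keep]
    y = df["event"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise RateModelError(
            f"zero events in stratum {condition}/{sex}; rate model is degenerate"
        )
    offset = np.log(t)

    if age_powers is not None:
        age_spec = default_age_spec(tuple(sorted(age_powers)))
        # keep explicit-power fits on the same band-midpoint convention
    elif select_powers:
        age_spec = select_fp_powers(df, "age", shift=0.5, scale=10.0)
    else:
        age_spec = default_age_spec()

    specs: dict[str, FPSpec] = {"age": age_spec}
    age_X = age_spec.design(df["age"].to_numpy(dtype=float))

    if "mm_count" in covariates:
        if mm_powers is not None:
            mm_spec = default_mm_spec(tuple(sorted(mm_powers)))
        elif select_powers:
            mm_spec = select_fp_powers(
                df, "mm_count", shift=1.0, scale=1.0, extra_design=age_X
            )
        else:
            mm_spec = default_mm_spec()
        specs["mm_count"] = mm_spec
        mm_X = mm_spec.design(df["mm_count"].to_numpy(dtype=float))
        X = np.column_stack([np.ones(len(df)), age_X, mm_X])
    else:
        X = np.column_stack([np.ones(len(df)), age_X])

    res = _poisson_deviance_fit(y, X, offset)
    cov = np.asarray(res.cov_params())
    cov = (cov + cov.T) / 2.0  # enforce symmetry for sampling

    return RateModel(
        sex=sex,
        condition=condition,
        specs=specs,
        params=np.asarray(res.params, dtype=float),
        cov=cov,
        age_support=(float(df["age"].min()), float(df["age"].max())),
        n_persons=int(len(df)),
        n_events=int(y.sum()),
        meta={
            "deviance": float(res.deviance),
            "converged": bool(res.converged),
            "power_selection": "explicit" if age_powers is not None else (
                "deviance_closed_test" if select_powers else "linear"
            ),
        },
    )


def fit_rate_model_pair(cohort, condition: str, covariates=frozenset({"age"}),
                        **kwargs) -> dict[str, RateModel]:
    """Fit both sexes for one condition; returns {'male': ..., 'female': ...}."""
    return {
        sex: fit_rate_model(cohort, condition, sex, covariates, **kwargs)
        for sex in ("male", "female")
    }
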