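"""Observed/expected SAE ratios, pooling and arm-level contrasts.

Per-trial ratios O/E get sampling-based 95% intervals: observed-count
uncertainty is drawn from the Jeffreys Poisson posterior Gamma(O + 0.5, 1)
and expected-count uncertainty from the rate-model coefficient draws; the
interval is the 2.5/97.5 percentile of the ratio of draws.

Per-condition pooling fits the random-effects Poisson model
``O_i ~ Poisson(E_i * exp(theta + b_i))``, ``b_i ~ N(0, tau^2)`` by maximum
marginal likelihood with adaptive Gauss-Hermite quadrature (Laplace-centred
nodes per study), giving a pooled ratio exp(theta) with a Wald interval
(a parametric bootstrap is available as an option).

Arm-level contrasts use the two-group Poisson log rate ratio with the
aggregate person-time formula per arm, and are combined across trials by
restricted-maximum-likelihood (REML) random-effects meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from saeratio.expectation import ExpectedCount, aggregate_person_time
from saeratio.trial_reconstruction import TrialSummary

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


class PoolingError(RuntimeError):
    """Raised when the random-effects fit cannot converge."""


@dataclass
class OERatioEstimate:
    """Observed/expected ratio for one trial with a sampling interval."""

    trial_id: str
    observed: int
    expected: float
    ratio: float
    lower: float
    upper: float
    n_draws: int
    seed: int | None = None
    basis: str = "age_sex"

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be nonnegative")
        if self.observed > 0 and not (
            self.lower <= self.ratio <= self.upper
        ):
            raise ValueError(
                f"trial {self.trial_id}: interval [{self.lower}, {self.upper}] "
                f"does not bracket ratio {self.ratio}"
            )


@dataclass
class PooledEstimate:
    """Pooled per-condition O/E ratio from the random-effects Poisson model."""

    condition: str
    ratio: float
    lower: float
    upper: float
    tau: float
    k: int
    log_ratio: float = 0.0
    se_log_ratio: float = float("nan")
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ArmComparison:
    """Two-group log rate ratio between trial arms."""

    trial_id: str
    comparison: str  # placebo | same-designation | experimental-vs-active
    log_rate_ratio: float
    se: float
    continuity_corrected: bool = False


@dataclass
class MetaResult:
    """Random-effects meta-analysis of per-trial effects."""

    estimate: float
    se: float
    lower: float
    upper: float
    tau2: float
    k: int
    method: str = "REML"
    passthrough: bool = False


def oe_ratio(
    observed: int,
    expected: ExpectedCount,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> OERatioEstimate:
    """Observed/expected ratio with a sampling-based 95% interval.

    The observed count is resampled as Gamma(observed + 0.5, 1) — the
    Jeffreys posterior for a Poisson mean — and divided by the expected
    draws (or the point expected when draws are absent); the interval is
    the central 95% of those ratio draws.  With observed = 0 the point
    ratio is 0 and the upper limit is driven by the Gamma(0.5, 1) tail.
    """
    if expected.expected <= 0:
        raise ZeroDivisionError(
            f"trial {expected.trial_id}: expected count is zero; the O/E ratio "
            "is undefined — check that the trial's age range overlaps the "
            "cohort support and person-time is positive"
        )
    rng = np.random.default_rng(seed)
    obs_draws = rng.gamma(shape=observed + 0.5, scale=1.0, size=n_draws)
    if expected.draws is not None and len(expected.draws) == n_draws:
        exp_draws = expected.draws
    elif expected.draws is not None and len(expected.draws) > 0:
        exp_draws = rng.choice(expected.draws, size=n_draws, replace=True)
    else:
        exp_draws = np.full(n_draws, expected.expected)
    ratio_draws = obs_draws / exp_draws
    lower, upper = np.percentile(ratio_draws, [2.5, 97.5])
    return OERatioEstimate(
        trial_id=expected.trial_id,
        observed=int(observed),
        expected=float(expected.expected),
        ratio=float(observed / expected.expected),
        lower=float(lower),
        upper=float(upper),
        n_draws=n_draws,
        seed=seed,
        basis=expected.basis,
    )


# ---------------------------------------------------------------------------
# random-effects Poisson pooling


def _marginal_nll(
    theta: float,
    tau: float,
    obs: np.ndarray,
    exp_: np.ndarray,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Negative marginal log likelihood via adaptive Gauss-Hermite quadrature.

    For each study the integrand over the random effect b is centred at its
    Laplace mode with matched curvature before applying the Hermite rule.
    """
    log_e = np.log(exp_)
    if tau < 1e-8:
        lam = np.exp(theta + log_e)
        ll = obs * (theta + log_e) - lam - _lgamma1p(obs)
        return -float(np.sum(ll))

    # Laplace mode per study: solve O - E e^{theta+b} - b/tau^2 = 0
    b = np.zeros_like(obs, dtype=float)
    inv_t2 = 1.0 / tau**2
    for _ in range(50):
        lam = np.exp(theta + log_e + b)
        g = obs - lam - b * inv_t2
        h = -lam - inv_t2
        step = g / h
        b_new = b - step
        # damp large Newton steps for stability
        b_new = np.clip(b_new, b - 2.0, b + 2.0)
        if np.max(np.abs(b_new - b)) < 1e-10:
            b = b_new
            break
        b = b_new
    sigma = 1.0 / np.sqrt(np.exp(theta + log_e + b) + inv_t2)

    # transformed nodes x = b + sqrt(2) sigma z  (shape k x q)
    x = b[:, None] + np.sqrt(2.0) * sigma[:, None] * nodes[None, :]
    lam = np.exp(theta + log_e[:, None] + x)
    log_f = (
        obs[:, None] * (theta + log_e[:, None] + x)
        - lam
        - _lgamma1p(obs)[:, None]
        - 0.5 * x**2 * inv_t2
        - np.log(tau)
        - 0.5 * np.log(2.0 * np.pi)
    )
    log_terms = (
        np.log(weights)[None, :] + nodes[None, :] ** 2 + log_f
        + 0.5 * np.log(2.0) + np.log(sigma)[:, None]
    )
    m = log_terms.max(axis=1)
    ll = m + np.log(np.sum(np.exp(log_terms - m[:, None]), axis=1))
    return -float(np.sum(ll))


def _lgamma1p(obs: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(obs, dtype=float) + 1.0)


def pool_oe(
    estimates: list[tuple[float, float]],
    condition: str = "",
    *,
    n_nodes: int = 30,
    interval: str = "wald",
    n_boot: int = 500,
    seed: int | None = None,
    log_expected_se: float = 0.0,
) -> PooledEstimate:
    """Pool per-trial (observed, expected) pairs for one index condition.

    Fits ``O_i ~ Poisson(E_i exp(theta + b_i))`` with ``b_i ~ N(0, tau^2)``
    by maximum marginal likelihood (adaptive Gauss-Hermite, ``n_nodes``
    nodes).  The pooled ratio is exp(theta) with a Wald 95% interval on the
    log scale; ``interval="bootstrap"`` replaces it with a parametric
    bootstrap percentile interval.

    ``log_expected_se`` propagates reference-rate uncertainty: the expected
    counts come from a fitted cohort model, and their shared (across-trial)
    log-scale standard error — e.g. the SD of log total expected over
    shared coefficient draws — widens the pooled interval in quadrature.
    """
    obs = np.array([o for o, _ in estimates], dtype=float)
    exp_ = np.array([e for _, e in estimates], dtype=float)
    if len(obs) == 0:
        raise ValueError("no trials to pool")
    if np.any(exp_ <= 0):
        raise ValueError("all expected counts must be positive")
    k = len(obs)

    if k == 1:
        o, e = float(obs[0]), float(exp_[0])
        theta = np.log(o / e) if o > 0 else -np.inf
        se = 1.0 / np.sqrt(o) if o > 0 else np.nan
        ratio = o / e
        lo = np.exp(theta - Z95 * se) if o > 0 else 0.0
        hi = np.exp(theta + Z95 * se) if o > 0 else np.nan
        return PooledEstimate(
            condition=condition, ratio=ratio, lower=lo, upper=hi, tau=0.0,
            k=1, log_ratio=theta, se_log_ratio=se,
            diagnostics={"note": "single trial; ratio passed through"},
        )

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    def nll(p: np.ndarray) -> float:
        return _marginal_nll(p[0], p[1], obs, exp_, nodes, weights)

    theta0 = float(np.log(max(obs.sum(), 0.5) / exp_.sum()))
    best = None
    for tau0 in (0.05, 0.3):
        res = optimize.minimize(
            nll,
            x0=np.array([theta0, tau0]),
            method="L-BFGS-B",
            bounds=[(-20.0, 20.0), (0.0, 10.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise PoolingError("random-effects Poisson fit failed")
    if not best.success and best.fun > nll(np.array([theta0, 0.0])) + 1e-6:
        raise PoolingError(
            f"non-convergence: best iterate {best.x}, "
            f"gradient norm {np.linalg.norm(best.jac):.3g}"
        )
    theta_hat, tau_hat = float(best.x[0]), float(best.x[1])

    # observed information by central differences
    h = 1e-4

    def d2(i: int, j: int) -> float:
        p0 = np.array([theta_hat, max(tau_hat, h)])
        e_i = np.zeros(2)
        e_j = np.zeros(2)
        e_i[i] = h
        e_j[j] = h
        pp = nll(np.clip(p0 + e_i + e_j, [-np.inf, 0], None))
        pm = nll(np.clip(p0 + e_i - e_j, [-np.inf, 0], None))
        mp = nll(np.clip(p0 - e_i + e_j, [-np.inf, 0], None))
        mm = nll(np.clip(p0 - e_i - e_j, [-np.inf, 0], None))
        return (pp - pm - mp + mm) / (4 * h * h)

    H = np.array([[d2(0, 0), d2(0, 1)], [d2(1, 0), d2(1, 1)]])
    se_theta = np.nan
    if tau_hat > 1e-4:
        try:
            cov = np.linalg.inv(H)
            if cov[0, 0] > 0:
                se_theta = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            pass
    if not np.isfinite(se_theta):
        se_theta = float(np.sqrt(1.0 / H[0, 0])) if H[0, 0] > 0 else np.nan
    se_interval = float(np.sqrt(se_theta**2 + log_expected_se**2))

    if interval == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            b = rng.normal(0.0, tau_hat, size=k)
            o_b = rng.poisson(exp_ * np.exp(theta_hat + b))
            try:
                r = optimize.minimize(
                    lambda p: _marginal_nll(p[0], p[1], o_b.astype(float), exp_,
                                            nodes, weights),
                    x0=np.array([theta_hat, max(tau_hat, 0.05)]),
                    method="L-BFGS-B",
                    bounds=[(-20.0, 20.0), (0.0, 10.0)],
                )
                boots.append(r.x[0])
            except Exception:  # pragma: no cover
                continue
        lo, hi = np.exp(np.percentile(boots, [2.5, 97.5]))
    else:
        lo = float(np.exp(theta_hat - Z95 * se_interval))
        hi = float(np.exp(theta_hat + Z95 * se_interval))

    return PooledEstimate(
        condition=condition,
        ratio=float(np.exp(theta_hat)),
        lower=lo,
        upper=hi,
        tau=tau_hat,
        k=k,
        log_ratio=theta_hat,
        se_log_ratio=se_theta,
        diagnostics={
            "nll": float(best.fun),
            "converged": bool(best.success),
            "n_nodes": n_nodes,
            "interval": interval,
            "log_expected_se": log_expected_se,
        },
    )


# ---------------------------------------------------------------------------
# arm-level contrasts


def arm_log_rate_ratio(summary: TrialSummary) -> ArmComparison:
    """Two-group Poisson log rate ratio between a trial's arms.

    Arms are grouped into a reference (placebo arms when present, else
    active arms in mixed-designation trials, else the first arm) and a
    comparator (all remaining arms pooled).  Person-time per group uses the
    aggregate formula; a 0.5 continuity correction is added to both counts
    when either is zero (flagged).
    """
    arms = summary.arms
    if len(arms) < 2:
        raise ValueError(
            f"trial {summary.trial_id}: arm comparison needs at least two arms"
        )
    designations = {a.designation for a in arms}
    if "placebo" in designations:
        comparison = "placebo"
        ref = [a for a in arms if a.designation == "placebo"]
        com = [a for a in arms if a.designation != "placebo"]
        if not com:  # all-placebo: fall back to first-vs-rest
            ref, com = [arms[0]], list(arms[1:])
    elif designations == {"experimental", "active"}:
        comparison = "experimental-vs-active"
        ref = [a for a in arms if a.designation == "active"]
        com = [a for a in arms if a.designation == "experimental"]
    else:
        comparison = "same-designation"
        ref, com = [arms[0]], list(arms[1:])

    def group(arms_):
        o = sum(a.sae_count for a in arms_)
        pt = sum(
            aggregate_person_time(a.n, summary.followup_days, a.sae_count)
            for a in arms_
        )
        return float(o), float(pt)

    o1, pt1 = group(ref)
    o2, pt2 = group(com)
    corrected = False
    if o1 == 0 or o2 == 0:
        o1, o2 = o1 + 0.5, o2 + 0.5
        corrected = True
        logger.warning(
            "trial %s: zero SAE count in one group; 0.5 continuity correction",
            summary.trial_id,
        )
    log_rr = float(np.log((o2 / pt2) / (o1 / pt1)))
    se = float(np.sqrt(1.0 / o1 + 1.0 / o2))
    return ArmComparison(
        trial_id=summary.trial_id,
        comparison=comparison,
        log_rate_ratio=log_rr,
        se=se,
        continuity_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# REML random-effects meta-analysis


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(
        0.5 * np.sum(np.log(v + tau2))
        + 0.5 * np.log(np.sum(w))
        + 0.5 * np.sum(w * (y - mu) ** 2)
    )


def meta_analyze(
    effects: list[tuple[float, float]], method: str = "REML"
) -> MetaResult:
    """Random-effects meta-analysis of (estimate, SE) pairs.

    Between-study variance tau^2 is estimated by REML (scalar bounded
    optimization of the restricted likelihood); the pooled effect is the
    inverse-variance weighted mean with weights 1/(SE^2 + tau^2) and a Wald
    95% interval.  A single effect passes through with a flag.
    """
    if method != "REML":
        raise ValueError("only REML is supported")
    y = np.array([e for e, _ in effects], dtype=float)
    se = np.array([s for _, s in effects], dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("all standard errors must be positive and finite")
    k = len(y)
    if k == 0:
        raise ValueError("no effects to pool")
    if k == 1:
        est, s = float(y[0]), float(se[0])
        return MetaResult(
            estimate=est, se=s, lower=est - Z95 * s, upper=est + Z95 * s,
            tau2=0.0, k=1, passthrough=True,
        )
    v = se**2
    upper_bound = max(10.0 * float(np.var(y, ddof=1)), 10.0 * float(v.max()), 1e-3)
    res = optimize.minimize_scalar(
        _reml_nll, args=(y, v), bounds=(0.0, upper_bound), method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(res.x)
    if _reml_nll(0.0, y, v) <= res.fun:
        tau2 = 0.0
    w = 1.0 / (v + tau2)
    est = float(np.sum(w * y) / np.sum(w))
    s = float(np.sqrt(1.0 / np.sum(w)))
    return MetaResult(
        estimate=est, se=s, lower=est - Z95 * s, upper=est + Z95 * s,
        tau2=tau2, k=k,
    )
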