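# Methods

This note documents the statistical model behind `saeratio`, the
conventions and numerical choices the implementation makes, what the
synthetic-data generator does and does not emulate, and the design of the
validation studies in `saeratio.experiments`.

## The model

### Reference rates

For each index condition and sex, first urgent hospitalisation or death in
the routine-care cohort is modelled as Poisson with a log person-time
offset:

    y_i ~ Poisson(mu_i),   log mu_i = beta' x(age_i [, mm_i]) + log t_i

where `y_i` is the 0/1 first-event indicator, `t_i` the person-days to the
event or to censoring, and `x(.)` a fractional-polynomial (FP) basis.  For
exponential event times censored at a fixed horizon, this Poisson
likelihood is exactly the constant-hazard survival likelihood, so the
fitted rate is the hazard per person-day.  Within an age band the
person-time-weighted rate N/T estimates the band's marginal hazard; this
is the quantity indirect standardization needs.

FP bases use the conventional power set {−2, −1, −0.5, 0, 0.5, 1, 2, 3},
with power 0 meaning log(x) and a repeated power p contributing
(x^p, x^p log x).  Power selection is an exhaustive deviance search over
all 8 FP1 and 36 FP2 candidates with a closed test: the best FP2 is kept
only when it improves on the best FP1 by more than the chi-square 0.05
critical value at 2 df, which in turn must improve on the linear model by
the same margin.  Strata with fewer than 50 events fall back to a linear
term with a warning.  Non-converging candidates are skipped, never fatal.

**Covariate conventions.** A recorded integer age `a` denotes the one-year
band [a, a+1); the model covariate is the band midpoint, implemented as a
+0.5 shift before dividing by 10 (the /10 scaling keeps coefficients per
decade and the argument strictly positive).  Both cohort fitting and all
rate predictions pass recorded ages/band labels, so the per-person (IPD)
and per-band (aggregate) standardization paths use one consistent
convention; mixing conventions (fitting on recorded age, predicting at
a+0.5) inflates aggregate expected counts by about half a year of age
slope (~2.5% here).  The multimorbidity count is shifted by +1 before FP
transforms because zero is a valid count.

### Age-band reconstruction

Registries report age as mean, SD, minimum and maximum, plus percent
female.  A truncated normal on [min, max] is solved (numerically, to 1e-6
in both moments, via a root find in (mu, log sigma)) so that its
*truncated* mean and SD match the report; band weights are its CDF
increments over integer-year bands, renormalized.  When no truncated
normal attains the reported SD — the supremum on an interval is the
uniform SD, (max−min)/√12 — a uniform distribution is used and flagged.
A missing SD is imputed as (max−min)/4 and flagged.  The same age
distribution is applied to both sexes (registries rarely stratify age by
sex), split by percent female: a recorded limitation.  Reconstruction is
deterministic.

### Expected counts

Aggregate trials: total person-time is
`followup × N − 0.5 × followup × events` (each incident event assumed to
occur midway through follow-up; floored at half the nominal person-time
when events exceed participants).  Cell person-time starts from the
headcount share `w_band × p_sex × followup × N`; the event-related deficit
is then apportioned across cells by *expected event share*
(w × p × rate), not by headcount.  Events concentrate where rates are
high, and those cells lose more person-time; headcount apportionment
overstated expected counts by 3–4% in calibration runs, while the
rate-weighted form is unbiased to within Monte-Carlo error.  With a
constant rate the two coincide and E = rate × total person-time exactly.

IPD trials: E = Σ_participants rate(age, sex[, mm]) × exposure days, with
exposure measured to the first event or censoring; no half-event
correction is needed.

### Interval estimation

Per-trial O/E intervals are sampling-based: the observed count is drawn
from Gamma(O + 0.5, 1) — the Jeffreys posterior for a Poisson mean — and
divided by expected-count draws obtained by pushing multivariate-normal
coefficient samples through the standardization; the interval is the
2.5/97.5 percentile of the ratio draws.  At O = 0 the point ratio is 0 and
the upper limit is driven by the Gamma(0.5, 1) tail.

Per-condition pooling fits

    O_i ~ Poisson(E_i exp(theta + b_i)),  b_i ~ N(0, tau^2)

by maximum marginal likelihood.  The marginal likelihood is computed by
adaptive Gauss–Hermite quadrature (default 30 nodes): per study the
integrand is centred at its Laplace mode (damped Newton, vectorized across
studies) with curvature-matched scaling, and summed on the log scale.
Optimization is L-BFGS-B over (theta, tau) with tau ≥ 0 from two starts;
the Wald interval uses the observed information by central differences
(falling back to the theta-block alone when tau sits at the boundary).  A
parametric-bootstrap percentile interval is available as an option.
tau = 0 is handled analytically (plain Poisson likelihood).

**Reference-rate uncertainty in the pooled interval.**  The offset model
treats E_i as known.  When the reference cohort is effectively infinite
relative to the trials (the realistic regime — millions of person-years
against hundreds of events per trial) that is harmless; with a finite
cohort the *shared* error of the fitted rate model shifts every trial's
E_i together and the offset-only Wald interval under-covers.  `pool_oe`
therefore accepts the shared log-scale SE of the total expected count —
computed by giving all trials one common set of coefficient draws and
taking the SD of log ΣE over draws — and adds it in quadrature.  The term
is recorded in the fit diagnostics and is ~1% for a 100k-person register,
vanishing as the register grows.

Arm contrasts use the two-group Poisson log rate ratio
ln((O₂/PT₂)/(O₁/PT₁)) with SE √(1/O₁ + 1/O₂), per-arm person-time from
the aggregate formula, and a 0.5 continuity correction on both counts when
either is zero (flagged).  Reference group: placebo arms when present,
else active arms in mixed experimental/active trials, else the first arm.
Random-effects meta-analysis (arm contrasts, per-trial multimorbidity
coefficients, interactions) estimates tau² by REML through bounded scalar
optimization of the restricted likelihood, with inverse-variance pooled
effects and Wald intervals; a single study passes through flagged.

### IPD analyses

Per-trial multimorbidity–SAE associations fit first-SAE ~ mm + age
(linear age: within-trial age ranges are narrow) with log time-at-risk
offset, per sex, and only in sex strata with ≥ 20 SAEs — the filter is
applied per sex, never per trial.  Strata with constant multimorbidity or
inestimable fits are skipped with a logged reason.  The arm×mm interaction
model adds arm, arm×mm and a sex adjustment; arm main effects come from
sex-stratified fits.  The dual standardization computes O/E under
age/sex and age/sex/multimorbidity reference models fitted to the same
cohort, pairing the two estimates per trial.

First-event (0/1) outcomes are used for association models, consistent
with the cohort's first-event definition; trial observed counts for O/E
are the per-participant SAE indicators summed.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with defaults
chosen as the study conditions:

- **Hazard.** Constant per-person hazard
  `0.20/365.25 × exp(0.40·(age−70)/10 − 0.10·female + 0.20·mm)` events per
  person-day: ~0.2 urgent hospitalisations/deaths per person-year for a
  70-year-old man without comorbidities, rising ~49%/decade of age and
  ~22% per comorbidity — magnitudes typical of chronic-disease registers.
  Event times are exponential, censored at 182 days (six months, matching
  both the routine-care observation window and the trials' median 26-week
  follow-up).
- **Ages.** Normal per condition profile, truncated to [18, 100], recorded
  in completed years.  Default profiles mirror large condition registers
  (COPD 69.1 ± 11.6, type 2 diabetes 65.3 ± 13.0, hypertension
  67.0 ± 12.9, asthma 45.6 ± 22.9, osteoarthritis 67.6 ± 12.7, dementia
  82.1 ± 9.0) with prevalences matching their share of a ~2.3M population.
- **Multimorbidity.** Poisson with mean `max(0, m₀ + 0.5·(age−50)/10)`
  (m₀ ≈ 1.5–2.5 by condition), capped at 20 — this age dependence plants
  exactly the age–multimorbidity confounding the dual standardization must
  disentangle.  Counts are realized as distinct medication-category flags
  over the 21-category scheme, excluding the person's own index-condition
  category (a comorbidity is a condition *other than* the index
  condition; a flag allows including it).
- **Trial selection.** Participants are sampled without replacement with
  inclusion odds `expit(mm_penalty × mm)` within age bounds
  (Efraimidis–Spirakis exponential race), and their SAE hazard is
  rescaled by the planted multiplier θ — the ground-truth O/E.  Trial
  summaries (age moments on band midpoints, as a registry summarising
  continuous age would publish; percent female; SAE count; arms) are
  tallied from the sampled IPD so reconstruction can be validated against
  truth.

Not emulated: diagnostic coding, deprivation/ethnicity structure,
recurrent SAEs (the generator is first-event only), informative dropout,
seasonal or secular rate trends, and between-trial differences in SAE
ascertainment.  Passing tests therefore show that the estimators recover
the truth *under the model's own assumptions* — proportional log-linear
hazards and exchangeable sampling — not that real trial/EHR data meet
those assumptions.

## Validation-study design

The studies in `saeratio.experiments` (run by `tests/test_acceptance.py`
and `scripts/acceptance.py`) use a single-condition register of 100,000
patients (COPD-like profile, prevalence 1.0) **regenerated per
replicate**, because a replicate is the whole experiment — cohort, model
fit, trial suite — and sharing one cohort across replicates would freeze
its sampling error into every replicate.  A single-condition register also
keeps reference-rate noise second-order relative to trial noise, mirroring
the real setting where the routine-care reference dwarfs any trial.

- *Calibration*: 200 replicates of a 20-trial suite (500 participants,
  26-week follow-up) with null selection and θ = 1; pooled- and per-trial
  interval coverage.
- *Recovery*: 50-trial suites with θ = 0.5 (mean pooled ratio over 5
  replicates) and θ = 0.85 (share of 25 replicates whose pooled interval
  excludes 1).
- *Decomposition*: 20-trial suites with mm_penalty = −0.35 at θ = 1
  (25 replicates) and θ = 0.8 (100 replicates); pooled ratios on both
  standardization bases and the per-trial direction
  ratio_mm > ratio_age/sex.
- *Model recovery*: one 100k register with full FP power selection;
  log-scale RMSE of the fitted rate curve over ages 40–90 against the
  analytic person-time-weighted marginal rate (the hazard marginalized
  over the Poisson multimorbidity distribution, weighting by expected time
  at risk), plus the REML-pooled multimorbidity coefficient from 30 trials
  against the planted 0.20.

The replicate studies fix linear age/multimorbidity terms — the generating
model's own functional form — so coverage and bias are measured for the
standardization and pooling machinery, not confounded with
power-selection variability; power selection is exercised separately.
Per-trial interval draws use S = 1,000 inside the replicate studies
(quantile Monte-Carlo error ≪ interval width) and S = 10,000 by default in
the API.

## Numerical choices and degenerate inputs

- Truncated-normal solve: `scipy.optimize.root` (hybr) in (mu, log sigma),
  1e-6 tolerance on both moments; midpoint-centred restart, then uniform
  fallback with a logged flag.
- Degenerate bounds (min = max) give a point-mass band; empty strata, zero
  events, zero exposure and expected = 0 raise explicit errors rather than
  returning silent zeros or infinities.
- Ages outside the fitted support ± 5 years are clamped with a warning.
- Covariance matrices are symmetrized before Cholesky sampling.
- Unknown medication tokens are ignored and logged once per token; a token
  on both the include and exclude lists, or mapped to two categories, is a
  validation error naming the offenders.
- All randomness flows through `numpy.random.default_rng` seeds recorded
  in outputs; reruns with equal seeds are bit-identical.

## Known limitations

- The aggregate path's person-time apportionment and the
  same-age-distribution-for-both-sexes assumption are approximations
  inherited from what registries report; both are flagged in output
  metadata where they fire.
- Wald intervals on the pooled log ratio approximate fully Bayesian
  credible intervals; the parametric bootstrap is available where the
  normal approximation is in doubt (small k, τ at the boundary).
- The bundled comorbidity map is synthetic: it covers the 21 categories
  with plausible medication-class tokens for testing and simulation and is
  not a clinically validated code list; real analyses must supply their
  own mapping TSV.
- Recurrent events are out of scope; observed counts exceeding N are
  accepted in aggregate inputs but the generator never produces them.
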