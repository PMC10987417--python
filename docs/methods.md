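# Methods

## Severity scoring and profile classification

The SCAT5 symptom checklist rates 22 symptoms on an integer 0–6 scale; the
injury severity score is their sum (0–132).  Severities must be integers —
SCAT5 is a Likert instrument, so fractional input is rejected rather than
rounded.

A clinical profile is operationalized as a subset of the 22 symptoms plus an
endorsement rule: a symptom is *endorsed* when rated at or above a minimum
severity (default 1), and profile *p* is present when the athlete endorses at
least `threshold(|S_p|)` of its defining symptoms `S_p`.  The default
threshold is `max(1, floor(n/2))` — the operationalization under which a
seven-symptom profile requires three endorsements.  A strict-majority
alternative (`ceil(n/2)`, selectable as `half_ceil` in the registry config)
requires four of seven.  Classification depends only on the endorsed/not
endorsed dichotomy; severity beyond the cut never affects membership, so the
assignment is monotone: raising any severity can only add profiles.

The symptom-to-profile mapping ships as YAML
(`src/concussion_profiles/data/default_registry.yaml`), not code.  The default
subsets approximate the AMSSM clinical-profile descriptions under two hard
constraints: the cognitive, anxiety/mood and ocular subsets contain exactly
seven symptoms, and every symptom belongs to the canonical 22-name
vocabulary.  Profiles intentionally share symptoms (e.g. concentration
difficulty appears in the cognitive, anxiety/mood and ocular subsets); no
down-weighting of shared symptoms is applied, and profiles are never ranked
as primary/secondary.  Research groups that operationalize the subsets
differently can drop in their own YAML without touching code.

## Cohort and outcomes

Day 0 is the injury day; the first evaluation must fall within 48 h (day ≤ 2).
Only episodes whose concussion mechanism is `sport` enter analysis; non-sport
and uncertain-origin injuries are excluded, with exclusion counts logged.
Free-text sport names collapse onto a configurable set of sport groups
(11 by default in the generator) so that mixed models have adequately sized
clusters; the mapping is an editable table with an `other` fallback.

**Time-to-recovery** is the day of the trajectory's final evaluation iff that
evaluation is asymptomatic (total severity 0 by default; a return-to-baseline
rule can be supplied as a predicate).  An athlete whose last observed
evaluation is symptomatic — including one who rebounded after a transient
zero — has no observed recovery and is treated as censored.  **Time-to-RTP**
is the recorded clearance day; when both are known RTP should not precede
recovery, and a violation is logged rather than silently corrected (the
record, not the reader, is wrong).

Descriptive summaries report per-profile counts, their percentage of an
explicit denominator (callers choose the policy; default is the table passed),
and the female/male split as a percentage of each profile's count, plus a
goodness-of-fit chi-square of the sex ratio against 1:1.

## Synthetic cohort generator

The generator emulates the statistical structure the downstream models
assume; its defaults are calibrations chosen once, not estimates.

Per athlete: sex ~ Bernoulli(0.5); sport group uniform over 11 groups; random
intercepts on the log-mean scale for sport group (SD 0.45) and athlete within
group (SD 0.9).  Expected total severity decays exponentially,
`mu(t) = 30 * exp(group + athlete intercepts) * exp(-0.18 t)`, and the observed
total is a zero-inflated NB2 draw (theta = 2, structural-zero probability
0.02) capped at 132.  Evaluations are emitted daily from day 0 until the
first zero-severity evaluation, which is the recovery day and final form
(hence a structural zero on day 0 is an immediate recovery), censored at 80
days.  RTP is recovery + 1 + Poisson(4) days.  Mechanisms mix sport /
non-sport / uncertain at 479:82:18 odds.

The severity total is allocated across the 22 symptoms by a weighted
multinomial draw with per-item cap 6 (overflow redistributed), so profile
co-occurrence rises mechanically with total severity — the relationship the
severity→profile-count model must recover.  Each athlete's allocation weights
are drawn once from a Dirichlet centred on the base weights
(concentration 0.6), giving athletes stable symptom phenotypes; without this,
severity spreads so evenly that every symptomatic athlete carries nearly every
profile.  The base weights up-weight common acute complaints (headache,
pressure in head, dizziness, concentration difficulty, fatigue).

Calibration targets (checked empirically at the defaults): day-0 mean
severity ≈ 35–45 (profile-conditioned means 30–50); day-14 expected decline
1 − e^(−2.52) ≈ 92%; median recovery ≈ 11 days with a right-skewed tail and
RTP ≈ 16–17 days; per-profile presentation probabilities ≈ 0.6–0.8; the
random intercepts account for roughly half of the variance explained by the
temporal severity model.  Optional knobs for power studies (`female_severity_log_ratio`,
`female_profile_weight_boost`) inject sex effects; the default is exactly
zero sex effect, which is what the type-I-error calibration of the pipeline
assumes.

What the generator does **not** emulate: within-day correlation of symptom
items beyond the shared total (the multinomial allocation is one defensible
choice); symptom rebound after recovery (trajectories end at the first zero);
multiple concussions per athlete; baseline (pre-season) symptom levels.
Passing tests on synthetic cohorts therefore validate the estimation and
classification machinery, not clinical claims about real athletes.

## Mixed-model estimation

No installed Python library fits zero-inflated negative-binomial mixed
models, so the engine is implemented here.  Families: Bernoulli, binomial(k),
Poisson, NB2 (variance mu + mu^2/theta) and ZINB
(`P(y) = pi 1[y=0] + (1-pi) NB2(y; mu, theta)`) with log link on mu and an
intercept-only logit zero-inflation component.  Random intercepts are
declared per grouping factor; "athletes nested in sport groups" is two
factors (sport group, athlete id) since athlete ids are globally unique.
Factors with fewer than two levels are dropped with a warning, which also
gives the single-group GLM reduction used as an oracle check.

The marginal likelihood integrates random effects by Laplace approximation:
for each candidate parameter vector, the penalized log-likelihood is
maximized over the random-effect vector by Newton iterations (sparse
`Z' W Z + D^{-1}` Hessian, dense Cholesky, Levenberg damping with |d2|
weights as a positive-definite surrogate for the few non-concave rows a ZINB
zero component produces), and the marginal objective is the penalized optimum
minus half the log-determinant of the true curvature at the mode.  Design
columns are standardized internally (undone on extraction) so the outer
problem is well conditioned.  Outer parameters (fixed effects, log variance
components, log theta, zero-inflation logit) are optimized by L-BFGS-B with
central-difference gradients from a GLM warm start, then polished with damped
Newton steps on a numerically differenced Hessian.  That Hessian's inverse
supplies Wald covariance for all parameters.  Convergence is judged on the
inference scale — the residual gradient norm must fall below
`max(1e-3, 1e-4 |loglik|)`, which bounds the implied likelihood shortfall far
under the ~0.5 corresponding to one standard error; failures restart from
seeded jittered starts and are never silent — fits carry `converged` and
`grad_norm`, and `variance_explained` refuses non-converged fits.  On Poisson mixed models the engine agrees with glmmTMB (the reference
implementation in R) to ~7 significant digits, and on fixed-effect-only
models with statsmodels GLM/ZINB to ≥ 4 decimals.

Nonlinear covariate effects use natural (restricted) cubic splines in
Harrell's parameterization: `df` columns, `df+1` knots at quantiles of the
training data (with an even-spacing fallback under heavy ties), linear beyond
the boundary knots; `df=1` degenerates to the plain linear column.  Spline
knots and categorical levels are frozen at fit time so prediction grids are
encoded exactly as the training data; extrapolation beyond the boundary knots
is flagged with a warning.

Conditional effects are population-level predictions (random effects at
zero): the inverse link of `x' beta` with delta-method 95% intervals computed
on the linear-predictor scale and transformed, which keeps the bounds
bracketing the estimate under the monotone link.  Variance explained follows
the Nakagawa decomposition on the linear-predictor scale with
distribution-specific residual variance (`pi^2/3` for logit models; the
log-normal approximation `ln(1 + 1/lambda + 1/theta)` for count models).
Sex contrasts report the response-scale difference, a delta-method CI and
two-sided Wald p-value, plus Cohen's d computed as the response-scale
difference over the pooled observed outcome SD (the d formula for GLMM
contrasts is a documented choice, not a canonical one).  Magnitude categories
(lower bound inclusive): d < 0.2 nominal, 0.2–0.5 small, 0.5–0.8 medium,
≥ 0.8 large; r < 0.7 nominal, 0.7–0.8 small, 0.8–0.9 medium, ≥ 0.9 large.
Per-count sex contrasts carry no multiplicity adjustment by default.

## Analysis pipeline

Cross-sectional stages consume only the initial-evaluation table (first form,
≤ 48 h) plus outcomes; repeated measures feed the temporal stage alone.

* **Temporal trends** — ZINB mixed models of daily severity and daily profile
  count on `ns(day, 3)` with nested random intercepts; reports the percent
  decline of the predicted mean from day 0 to day 14 and linear-time
  comparison fits.  Profile counts are modeled as ZINB like severity (0–6
  counts with excess zeros late in recovery).
* **q1** — per profile, Bernoulli mixed model `present ~ sex + (1 | sport
  group)`; predicted per-sex probabilities, contrast p, Cohen's d.
* **q2 / q3** — per profile, NB2 mixed models of initial severity / observed
  recovery days on sex.  Right-skewed day counts motivate NB2; censored
  recoveries are excluded with counts logged.  Athletes with several profiles
  enter each profile's model (profiles are not mutually exclusive).
* **q4** — binomial(6) mixed model `n_profiles ~ ns(severity, 3) * sex`; the
  saturating logistic shape caps predictions at six profiles.  Outputs the
  per-sex curve, a joint Wald test of the spline-by-sex interaction, variance
  explained, and the severity band edges where the rounded sex-averaged
  predicted count leaves 0–1 and reaches 6.
* **q5** — NB2 mixed models `recovery ~ ns(n_profiles, 3) * sex` and likewise
  for RTP; per-count sex contrasts at integer counts 0–6 (counts without
  observations are skipped), and per-sex marginal means averaging the fitted
  curve over the observed profile-count distribution.

`run_pipeline` wires the stages behind a validated YAML config (unknown keys
rejected at every level), logs stage timings and exclusion counts, and emits
a deterministic JSON report — reports are byte-identical across runs with the
same seed, which is why timings live in the log and not the report.

## Problem sizes and numerical choices

The default synthetic analysis cohort is 500 athletes (~5,000 daily
evaluations, ~400 athlete-level random effects), which one full ZINB-spline
fit handles in about a minute.  Estimator calibration uses 200 simulated
ZINB-GLMM datasets of 300 observations in 10 clusters (the smallest
identifiable design for the family), and the pipeline's type-I-error check
uses 100 replicate cohorts of 300 athletes with the no-sex-effect generator.
Spline df defaults to 3 everywhere; optimizer bounds keep log-variances in
[−12, 6] and log-theta in [−4, 10]; the inner Newton solves to an absolute
gradient tolerance of 1e-10 with line-search backtracking.

## Known limitations

* Zero-inflation is intercept-only; covariate-dependent structural zeros are
  out of scope.
* No random slopes, crossed random effects, GEEs, or Bayesian estimation.
* The default registry is one defensible transcription of the profile
  taxonomy; substantive conclusions about real cohorts should be checked
  under alternative registries.
* Wald inference relies on a numerically differenced Hessian; in tiny samples
  or at variance boundaries profile-likelihood intervals would be more
  reliable.
* Recovery is defined by the final evaluation's asymptomatic status, so
  irregular follow-up schedules shift observed recovery days.
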