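# Methods

## Scope and data flow

The pipeline runs in five stages: (1) synthetic cohort generation, (2)
epoch preprocessing and valid-day quality control, (3) rest–activity rhythm
(RAR) parameter extraction, (4) cohort assembly (tertiles, inflammation
indices, activity categories, polygenic-score groups), (5) inference —
proportional-hazards estimation, interaction/mediation, and boosted
survival prediction. Stages 2–5 never read the generator's ground-truth
table; it exists solely so tests can measure recovery.

## Synthetic cohort generator

The generator defines the study conditions under which everything is
tested, so its defaults are documented choices, not tunables.

**Diurnal curve.** Each participant has an anti-logistic activity curve
`y(t) = min + amp·F(cos(2π(t−φ)/24))`, `F(c) = expit(β(c−α))`. Population
distributions: `min ~ N(10, 3²)` mg truncated at 0; `amp ~ N(45, 12²)` mg
truncated at 0; `φ ~ N(14 h, 1.2²)` wrapped; `α ~ N(−0.4, 0.15²)` clipped to
(−0.95, 0.95) — α = −0.4 puts the above-mesor (active) period at ≈15 h,
matching ~9 h of rest; `β ~ lognormal(log 8, 0.4)`. The steepness centre of
8 reflects the switch-like character of human wake/sleep transitions
(roughly 1–2 h from rest-level to active-level activity); a shallow β ≈ 2
would stretch that transition over 5–6 h and also makes `amp` and `β`
jointly weakly identified (a flat likelihood ridge), which is a property of
the model worth knowing when interpreting fitted amplitudes from
low-steepness individuals.

**Noise.** Default minute noise is multiplicative log-normal driven by an
AR(1) process: `value = curve · exp(σ a_t − σ²/2)` with unit-variance AR(1)
`a_t` (ρ = 0.5) and σ = 1.4. This family is mean-preserving, nonnegative
and right-skewed, like real minute-level wrist acceleration where brief
movement bursts dwarf the diurnal mean. σ was calibrated so that the
cosinor pseudo-F of a default 7-day series lands in the tertile band
reported for population actigraphy (tertile means ≈56/85/123 here), with
hourly-bin IS ≈ 0.6 and IV ≈ 1.0 — the regime in which the downstream
analyses operate in practice. An additive truncated-Gaussian AR(1) variant
(`NoiseConfig(kind="additive")`) is retained; it is convenient for
closed-form residual checks but cannot reach realistic noise levels
without truncation bias, which is why it is not the default.

**Missingness.** Contiguous blocks per day (Poisson count, uniform start,
geometric length, defaults 0.5 h/day expected with 30-min mean blocks) are
flagged imputed and filled with the participant's time-of-day mean,
mimicking an upstream imputation step without reproducing any specific
algorithm.

**Covariates and outcome.** Demographics and lifestyle are drawn from
distributions matching a population accelerometer cohort (age N(56.3, 7.8²)
truncated 40–70, 43.9 % male, smoking 39/54/7 % never/former/current, BMI
N(26.7, 4.4²), etc.). PRS ~ N(0, 1); its default log-hazard per SD is
log(3.01) divided by the top-vs-bottom tertile mean gap of a standard
normal (≈2.18), so the top-vs-bottom PRS-tertile hazard ratio is ≈3.
Event times are exponential with hazard `h₀·exp(lp)` (Weibull behind a
config switch), administratively censored at 10.1 years; `h₀` defaults to
0.000297/year (~0.3 % cumulative incidence) and `event_target` rescales it
so a requested expected event count is reached — tests at n = 10–20 k use
300–500 events because 0.3 % of 20 k (~60 events) is underpowered for
tertile contrasts. The linear predictor is centred so `h₀` refers to the
average participant.

**Mediation design.** The continuous exposure is `z_weak`, the negated
amplitude in population-SD units. The mediator path adds `a·z_weak` to the
neutrophil count (and a proportionally scaled amount to monocytes); the
outcome model adds `b·(neutrophils − 4)` and a direct term `c′·z_weak`.
The designed proportion mediated is `a·b/(a·b + c′)`; defaults (a = 0.3,
b = 0.0737, c′ = 0.38) give 0.055. Weaker rhythm → higher inflammatory
counts, the direction of the hypothesized biology.

## Preprocessing

Sub-minute epochs are averaged to minutes (a minute is imputed if any
constituent epoch is); a day is valid iff all 1,440 minute slots are
present and < 4 h are imputed (strict inequality: 3.98 h is valid, 5 h is
not); participants need ≥ 3 valid days. Days are calendar days from the
series start; partial first/last days are incomplete rather than padded, to
avoid biasing the 24-h profile. Any 3 valid days qualify — consecutiveness
is not required.

## RAR parameters

The cosinor fit uses bounded nonlinear least squares (trust-region
reflective) on the non-imputed minutes of valid days with their clock
times. Initialization: min = 5th percentile, amp = 95th − 5th percentile,
φ = smoothed hour-of-day profile maximum, α = 0, β = 2; bounds amp ≥ 0,
β ∈ (0, 1000], α ∈ (−0.999, 0.999), φ ∈ [0, 24); up to 10 jittered restarts
on non-convergence (the model is multimodal in (α, β)). A constant series
yields the degenerate fit (amp = 0, pseudo-F = 0, crossing times NaN)
rather than an exception. Up-/down-mesor are the ascending/descending
mesor-crossing clock times, found on a 1-min grid and refined by
bisection; pseudo-F uses p = 5 free parameters:
`((RSS₀ − RSS)/(p−1)) / (RSS/(n−p))`.

IS/IV follow the standard hourly-bin formulas (p = 24 slots); a constant
series reports IS = IV = 0 with a degeneracy flag. L5/M10 scan all 1,440
circularly wrapped windows of the averaged day profile (ties → earliest
start after midnight); L5 start is reported as signed hours from midnight
in [−12, 12) because the least-active period spans midnight. Imputed
minutes contribute to the profile by default (`exclude_imputed` gives the
sensitivity variant).

## Cohort assembly

Tertiles use linear-interpolation empirical quantiles at 1/3 and 2/3 with
left-closed intervals (ties to the lower tertile) — with all-distinct
values the three groups differ by at most the n mod 3 remainder. The
reference tertile is fixed per parameter (lowest-risk convention). SIRI =
neutrophils × monocytes / lymphocytes; SII = neutrophils × platelets /
lymphocytes. MVPA: active iff ≥ 150 min/week; among the active, weekend
warrior when the top-2 days carry ≥ 50 % of the weekly total.

## Survival inference

Cox models use lifelines with the Efron tie approximation. Model 1 adjusts
age + sex; Model 2 adds education, employment, deprivation, shift work,
BMI, seven medical-history flags, smoking (two dummies), diet, alcohol and
statin/vitamin use. Trend p comes from refitting with the integer-scored
tertile (1/2/3); BH adjustment is applied across the 13 RAR parameters
within each model. The Schoenfeld p is a global rank-transform test over
the exposure terms. A warning flag is raised when events per parameter
< 10. Restricted cubic splines use 4 knots at the 5/35/65/95th percentiles
(3-knot fallback on collinearity); nonlinearity is a likelihood-ratio test
of the nonlinear basis terms, and the curve is re-referenced so log-HR = 0
at the median exposure. The Fine–Gray fit implements Geskus
censoring-weighted risk-set expansion (competing-event subjects remain at
risk with weight G(t)/G(s) from the Kaplan–Meier censoring distribution)
on lifelines' time-varying Cox; with no competing events it reduces
exactly to the Cox model. Model-based (not robust) standard errors are
reported for the weighted fit. Subgroup analyses refit Model 2 within
strata (suppressed below 10 events) with a cross-product Wald interaction
test; for the sex subgroup the stratum indicator replaces the collinear
sex adjuster.

## Interaction and mediation

RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1 is computed from one fitted model's joint
indicator grid; its CI uses the delta method on the log-HR covariance
(gradient (−HR₁₀, −HR₀₁, HR₁₁)). Tertiled exposures collapse to the
high-risk extreme vs reference for the 2×2 grid. Joint-effect grids fit
the full cross-classification in a single adjusted model and re-reference
all cells to the smallest fitted coefficient, so the lowest-risk cell has
HR exactly 1 (the co-factor is removed from the adjustment set when it is
the co-factor under study).

Mediation uses a linear mediator model and a Cox outcome model; with a
~0.3 % outcome the log-hazard scale approximates the log-risk scale, so
ACME = a·b, ADE = c′ and proportion mediated = ACME/(ACME + ADE) (the
product-of-coefficients decomposition). Point estimates are the analytic
products (deterministic); uncertainty comes from 1,000 quasi-Bayesian
draws of both models' coefficients from their asymptotic normals, with an
optional nonparametric bootstrap for the proportion-mediated CI.
Exposures enter standardized and negated (higher = weaker rhythm). A
proportion outside [−1, 2] is reported with an instability warning — the
ratio is ill-behaved when the total effect is near zero. No
exposure–mediator interaction terms are modeled, and the generator uses
the causal ordering the analysis assumes (in observational data measured
mediators may precede the exposure — a known caveat).

## Boosted survival ladder

Four nested XGBoost models (`survival:cox` objective, depth 3, η = 0.05,
subsample/colsample 0.9, min_child_weight 5) on one 70/30 event-stratified
split with early stopping (patience 50, cap 500 rounds) on the held-out
partial likelihood: baseline covariates; +PRS; +RAR; +PRS+RAR. Evaluation
uses an event-within-horizon binary label (horizon = max follow-up;
participants censored earlier are excluded): AUC on the margin, Brier
score on the absolute risk `1 − exp(−H₀(h)·exp(margin))` with a Breslow
baseline from the training split, decile calibration, and decision-curve
net benefit `TP/n − FP/n·p_t/(1−p_t)` on p_t ∈ (0, 0.2] (capped because
the outcome is rare). 5-fold CV repeats the whole ladder per fold.
Attribution is exact TreeSHAP on the log-hazard margin via XGBoost's
`pred_contribs`; local accuracy (base value + row contributions = margin)
holds by construction and is asserted to 1e-4.

## What passing tests do and do not show

The generator emulates the *structure* of accelerometer cohort data —
diurnal shape, noise magnitude (calibrated to realistic pseudo-F/IS/IV
ranges), missingness bookkeeping, rare proportional-hazards outcomes and a
planted mediation pathway. It does not emulate sleep architecture,
activity-type composition, device calibration artifacts, heavy-tailed
covariate dependence, or informative censoring. Recovery results therefore
validate the estimators under correctly specified models of realistic
magnitude; they do not certify robustness to the misspecifications real
cohorts contain. Known limitations: amplitude/β weak identifiability at
low steepness; Fine–Gray standard errors are model-based rather than
robust; the single-AUC evaluation is horizon-label-based rather than a
time-dependent estimator; mediation assumes no unmeasured
exposure–mediator confounding.

## Problem sizes

Replicate studies run at n = 2,000–20,000 with event counts inflated to
80–500 (see `event_target`), chosen so coverage, type-I-error and FDR
checks are informative at desk scale; single-fit examples use n = 20,000
with ~450 events.
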