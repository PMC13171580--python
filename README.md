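# actirisk

Rest–activity rhythms (RAR) derived from wrist-worn accelerometers summarize
the strength, timing and fragmentation of a person's 24-hour behavioral
cycle. `actirisk` implements a complete epidemiological pipeline that asks
whether weak rhythms predict a rare vascular outcome — abdominal aortic
aneurysm (AAA) — and by which pathways: it extracts thirteen RAR parameters
from minute-level activity series, fits tertile-based Cox proportional-hazards
models with false-discovery-rate control, quantifies additive interaction
(RERI) and joint effects with smoking and polygenic risk, estimates mediation
through inflammatory blood markers, and trains a gradient-boosted survival
prediction ladder explained with TreeSHAP.

Because population accelerometer cohorts are access-restricted, the package
ships a first-class synthetic cohort generator with known ground truth: 7-day
minute-level activity traces with an anti-logistic diurnal shape, realistic
multiplicative noise, imputed-block missingness, covariates, a polygenic
score, inflammatory markers partially driven by rhythm strength, and
proportional-hazards event times (~0.3 % 10-year cumulative incidence by
default, inflatable for desk-scale power). Every inference stage is validated
against this generator's ground truth; the generator is never consulted by
the inference code itself.

## The models

**Extended (anti-logistic) cosinor.** Activity at clock time *t* (hours) is

```
y(t) = min + amp · F(cos(2π(t − φ)/24)),   F(c) = 1 / (1 + exp(−β(c − α)))
```

with lower asymptote `min` (mg), amplitude `amp`, acrophase `φ` (peak time),
width `α ∈ (−1, 1)` and steepness `β > 0`. Derived: mesor = min + amp/2,
up-/down-mesor (mesor-crossing clock times) and a pseudo-F goodness-of-rhythm
statistic vs the constant-mean model.

**Nonparametric metrics.** Interdaily stability (IS) and intradaily
variability (IV) on hourly bins; L5/M10 (least-active 5 h, most-active 10 h
of the averaged 24-h profile, scanned over all 1,440 wrapped windows);
relative amplitude RA = (M10 − L5)/(M10 + L5); L5/M10 start times, with L5
start expressed as signed hours from midnight.

**Inference.** Each parameter is tertiled with the lowest-risk tertile as
reference (T1 for IV, L5, L5 start; T2 for up/down-mesor, acrophase, M10
start; T3 for the rest). Cox models: Model 1 (age + sex) and Model 2 (full
adjustment); trend tests by integer-scored tertile; Benjamini–Hochberg across
the 13 parameters per model; Schoenfeld diagnostics, restricted cubic
splines, 1-year landmark, Fine–Gray subdistribution hazards (Geskus
weighting), subgroup interactions. RERI = HR₁₁ − HR₁₀ − HR₀₁ + 1 with
delta-method CIs; mediation via the product-of-coefficients decomposition
under the rare-disease approximation with quasi-Bayesian Monte-Carlo CIs.

## Worked example

```python
import numpy as np
from actirisk import SimConfig, simulate_cohort, make_tertiles, fit_cox
from actirisk.simulate import EffectConfig

cfg = SimConfig(
    n_participants=20000, seed=1,
    effects=EffectConfig.null(rar_t1_loghr=np.log(1.5)),
    event_target=450,                      # inflate the rare outcome for power
)
cohort, _, truth = simulate_cohort(cfg, with_activity=False)
exposure = make_tertiles(cohort["amplitude"], "amplitude")
res = fit_cox(cohort, exposure, model_tag="M0")
print(f"T1 vs T3: HR {res.hr['T1']:.2f} "
      f"({res.ci_low['T1']:.2f}-{res.ci_high['T1']:.2f}), "
      f"p-trend {res.p_trend:.2g}")
```

```
T1 vs T3: HR 1.40 (1.13-1.74), p-trend 0.0013
```

The generator planted a true T1-vs-T3 hazard ratio of 1.50 for the lowest
amplitude tertile; the fitted model recovers 1.40 with a confidence interval
covering the truth, and the dose–response trend across tertiles is strongly
significant at ~450 events.

The same objects drive the rest of the pipeline: `mediate()` returns the
proportion of the rhythm–outcome association transmitted through an
inflammatory marker, `interaction_2x2()` the departure from hazard
additivity, and `fit_ladder()`/`evaluate()`/`explain()` the four-model
XGBoost survival comparison with per-feature log-hazard attributions.

A command-line interface mirrors the library:

```bash
actirisk simulate --n 500 --seed 1 --out data/
actirisk preprocess --in data/epochs --out prep/
actirisk rar --in prep/ --out rar_metrics.csv
actirisk cohort --rar rar_metrics.csv --covariates data/cohort.csv --out cohort.csv
actirisk cox --cohort cohort.csv --models m1,m2 --out results/
```

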