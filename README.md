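# glyctraj

Latent-class modelling of longitudinal HbA1c trajectories from the time of
type 2 diabetes diagnosis, and quantification of their association with the
first hospitalization for heart failure (HHF).

## Who this is for

Epidemiologists and biostatisticians working with diabetes-registry data:
per-subject HbA1c laboratory series on irregular schedules, demographics,
prior-complication flags, and right-censored first-HHF outcomes.  The
package provides the full analysis chain — cohort construction, trajectory
clustering, survival association, and sensitivity/validation analyses —
plus a synthetic-registry generator so the entire pipeline can be exercised
and tested without access to protected health data.

## The model

**Trajectory classes.**  Latent class growth analysis (LCGA): the cohort is
a finite mixture of K classes, each following a fixed-effect mean curve on a
time basis x(t) (linear, quadratic, cubic, logarithmic `(1, log(t+1))`, or
exponential `(1, e^{-t/26})`, t in weeks from diagnosis).  For subject i
with measurements y_ij at times t_ij,

    L_i = Σ_k π_k Π_j N(y_ij | x(t_ij)ᵀ β_k, σ²)

with mixing proportions π_k (intercept-only multinomial logit) and shared
residual SD σ.  Estimation is EM with a burn-in-then-refine multi-start;
model selection combines BIC, `-2ℓ + p·log(n)`, with a 3% minimum-class-
proportion rule, with 10-fold subject-level cross-validation available as
corroboration.  Separation diagnostics: average posterior probability of
assignment (APPA) and scaled entropy `1 − Σᵢₖ(−p_ik log p_ik)/(n log K)`.

**Time origin.**  All clocks start at the diabetes diagnosis date (DDD).
When the first HbA1c specimen falls in the diagnosis year, DDD is that
specimen's date; otherwise it is imputed uniformly over the days of the
diagnosis year (deterministic per subject given a seed), and the stability
of results under re-imputation is itself one of the pipeline's analyses.

**Survival.**  Kaplan–Meier curves, the G-sample log-rank test, Cox
proportional hazards with Efron tie handling (Newton–Raphson, Wald CIs) and
Harrell's concordance index are implemented from first principles; the test
suite cross-checks them against `lifelines` and hand-computed tables.  The
Cox model adjusts class indicators for sex, ethnicity, age at diagnosis and
ten prior-complication flags (with an explicit missing-flags indicator).

## Worked example

```python
import numpy as np
from glyctraj import (default_registry_config, generate_cohort,
                      build_cohort, fit_em, BasisSpec)
from glyctraj.survival import logrank_test

cfg = default_registry_config(n_subjects=2000, seed=1)
registry = generate_cohort(cfg)                      # 3 CSV-shaped tables
cohort = build_cohort(registry.measurements, registry.subjects,
                      registry.events, rng_seed=1)
print(f"eligible subjects: {len(cohort)} of {cfg.n_subjects}")

fit = fit_em(cohort, BasisSpec("logarithmic"), k=5, n_starts=10, seed=1)
print("class proportions:", np.round(fit.class_proportions, 3))
print("APPA:            ", np.round(fit.appa, 3))
print(f"scaled entropy:   {fit.scaled_entropy:.3f}")
print("intercepts:      ", np.round(fit.params.beta[:, 0], 2))

times = np.array([s.event_weeks for s in cohort.subjects])
events = np.array([s.event_indicator for s in cohort.subjects])
lr = logrank_test(times, events, fit.modal_class)
print(f"log-rank chi2 = {lr.statistic:.2f} (df={lr.df}, p={lr.p_value:.4f})")
```

prints

```
eligible subjects: 1809 of 2000
class proportions: [0.034 0.098 0.421 0.093 0.353]
APPA:             [1.    0.996 0.98  0.917 0.992]
scaled entropy:   0.968
intercepts:       [10.64  8.65  7.16  7.7   6.24]
log-rank chi2 = 3.18 (df=4, p=0.5288)
```

Classes are canonically ordered by descending mean fitted HbA1c, so class 1
here is the small high-decreasing group (3.4%, intercept 10.6) and class 5
the large low-stable group.  The fitted proportions and intercepts recover
the generating five-class population; every APPA exceeds 0.9, indicating
clean separation.  At n=2000 only ~35 HHF events exist, so this particular
seed's omnibus log-rank is not significant — the class-wise hazard gradient
becomes significant at registry scale.

The same stages are scriptable from the shell:

```bash
glyctraj simulate --n-subjects 2000 --seed 1 --out runs/sim
glyctraj select   --input-dir runs/sim --out runs/sel --k-max 7 --n-starts 5
glyctraj associate --input-dir runs/sim --out runs/assoc --shape logarithmic --k 5
glyctraj sensitivity --input-dir runs/sim --out runs/sens --shape logarithmic --k 5
glyctraj validate --input-dir runs/sim --out runs/val --shape logarithmic --k 5
```

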