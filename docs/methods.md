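# Methods

## Model

The population model is latent class growth analysis (LCGA), i.e.
group-based trajectory modelling: a finite mixture of K classes, each with a
fixed-effect mean curve over time and no random effects.  Subject i with
measurements y_ij at weeks t_ij from the diabetes diagnosis date contributes

    log L_i = log Σ_k π_k Π_j N(y_ij | x(t_ij)ᵀ β_k, σ²).

Assumptions: within a class, all residual variation around the class curve
is independent Gaussian noise with a shared SD σ (a config flag enables
class-specific σ_k); class membership does not depend on covariates (the
mixing model is intercept-only); visit times are non-informative.

Time bases (t in weeks, s = t/`time_scale`, default 100):

| shape       | x(t)               |
|-------------|--------------------|
| linear      | (1, s)             |
| quadratic   | (1, s, s²)         |
| cubic       | (1, s, s², s³)     |
| logarithmic | (1, log(t + 1))    |
| exponential | (1, e^(−t/26))     |

The `+1` in the log link makes t = 0 admissible; the 26-week decay constant
of the exponential link concentrates its action in roughly the first 30
weeks after diagnosis.  Both constants are config-exposed
(`BasisSpec.time_scale`, `BasisSpec.exp_timescale_weeks`).

## Estimation

EM with a burn-in-then-refine multi-start.  The M-step is exact: π_k is the
mean posterior, β_k the posterior-weighted least-squares solution pooling
all of a subject's measurements at its posterior weight, σ² the pooled
weighted mean squared residual (floored at 1e-12 against degenerate
collapse).  The E-step works in log space via log-sum-exp, so subjects with
many measurements do not underflow.

Initialization: start 1 is deterministic — the global (K=1) least-squares
curve replicated K times with ordered intercept offsets placed at the
2%…98% quantiles of the subject-level mean residuals.  Tail-anchored
quantiles matter: rare classes sit in the extremes of the level
distribution, and with few random starts a symmetric initialization
frequently leaves one component empty at the true K, which would corrupt
the minimum-proportion selection rule.  Starts 2..n perturb start 1 with
Gaussian noise scaled to the residual SD and to each basis column's RMS.
Each start runs 30 burn-in iterations (config); the best burn-in
log-likelihood is refined until the relative log-likelihood change is below
1e-6 (config) or 500 iterations, in which case `converged=False` is flagged
rather than raised.  EM traces are retained on the fit object so
monotonicity is assertable.

Label switching is resolved deterministically by relabelling classes in
descending order of mean fitted level over the observed time grid; class 1
is therefore always the highest trajectory and class K the lowest.  When
classes must be identified across two *different* fits (re-baselined,
re-seeded, or train-vs-full fits), a one-to-one Hungarian assignment on the
L2 distance between mean curves over a common grid (0–250 weeks, 26 points)
is used instead; relabelled-fit comparisons are only meaningful through
this matching.

`bic = −2ℓ + p·log(n)` uses the number of *subjects* n (the mixture's
independent units), not measurements; p = K·d + (K−1) + 1 for shared σ.

## Model selection

Every (shape, K ≤ k_max) cell is fitted.  A cell is admissible when its
smallest modal-assignment class proportion is ≥ 3% (the proportion type is
switchable to the estimated π_k).  The chosen K is the largest K at which
*every* shape is still admissible; the shape then minimizes BIC at that K.
Subject-level K-fold cross-validation (mean held-out per-subject mixture
log-likelihood) is recorded per cell when `cv_folds ≥ 2`, as corroboration
only — it never overrides the BIC + proportion rule, so the default
pipeline runs omit it for speed.

The 3% rule sits on a sampling cliff when the smallest true class is 3.4%:
at n ≈ 2000 the realized share of that class has SD ≈ 0.4 points, so in a
minority of datasets every shape's fitted minimum proportion honestly drops
below 3% and the rule selects a smaller K.  This is expected behavior of
the rule, not an estimation failure.

## Cohort construction

Eligibility requires ≥ 5 HbA1c measurements spanning ≥ 3 years, with 3
years taken as 3 × 365.25 = 1095.75 days (leap-year neutral).  The
diagnosis date (DDD) equals the first specimen date when both fall in the
same calendar year; otherwise it is drawn uniformly on day offsets
{0,…,364} of the diagnosis year — 364, not 365, so the date never
overflows a non-leap year.  The draw is a pure function of (seed, subject
id), so imputation does not depend on iteration order.  Measurements that
predate an imputed DDD are dropped (the basis functions require t ≥ 0 and
the DDD is the trajectory origin) and eligibility is re-checked.
Event-free subjects are censored at their last measurement by default; a
config override (`censor_at="events_table"`) uses the events-table
censoring date instead.  Missing prior-complication flags are retained as
an explicit missing level, never dropped.

## Survival estimators

All estimators are written from first principles (an established package
serves only as an independent oracle in the tests).  Cox regression uses
the Efron tie correction — week-resolution times tie frequently and Efron
is the modern default — maximized by Newton–Raphson with step-halving;
covariance is the inverse observed information; CIs and p-values are Wald.
Constant covariate columns are dropped with a warning; diverging
coefficients (monotone likelihood) raise an error naming the covariate.
Harrell's C counts pairs (t_i < t_j, event_i) plus tied-time event-vs-
censored pairs, with ½ credit for tied risk scores — the same convention as
`lifelines`, which the tests match to 1e-9.

At desk-scale cohorts (n ≈ 2000, ~2% cumulative incidence) the Table-style
covariate set is larger than the event count supports.  The pipeline
therefore removes, per fit, any 0/1 indicator with zero events among its
carriers or its non-carriers — exactly the columns whose partial-likelihood
MLE is infinite — and any column that is collinear within the realized
cohort (pivoted-QR check).  At registry scale nothing is removed; at small
n this keeps risk ranking from being dominated by unidentifiable ±∞
coefficients.  The Cox reference class is configurable and defaults to the
lowest-trajectory class.

## Synthetic registry generator

The generator emulates a hospital diabetes registry of newly diagnosed
type 2 diabetes patients with five latent trajectory classes.  Anchored
characteristics (class shares 35.5/41.1/3.4/10.7/9.2%; baseline HbA1c
means 6.23/7.16/10.6/7.69/8.73%; cumulative HHF incidence
1.43/1.05/3.37/2.89/3.55% over mean follow-ups of 239.9–252.8 weeks;
age, sex, ethnicity and prior-complication mixes per class; ~15.2 visits
per subject; 19% of subjects with first specimen in the year after
diagnosis; 13% of subjects with missing complication flags).  Each class's
constant HHF hazard is solved in closed form from its cumulative incidence,
λ = −log(1−p)/t̄.

Free modelling choices, set once: log-basis slopes
(−0.04, −0.05, −0.33, −0.26, −0.20) and residual SDs
(0.40, 0.45, 0.90, 0.50, 0.65).  The slope/SD pair of the sharp-decline
class was chosen so that (a) it crosses the stable class's curve early and
ends near the lowest class — which reproduces the re-baselining behavior in
which its members re-group into the stable and low classes — and (b) the
five classes are statistically identifiable at n = 2000 with ~15 visits,
i.e. the mixture MLE actually sits at the generating structure.  A
shallower decline with larger noise makes that class formally present but
unidentifiable from the stable class at this sample size (EM started at the
truth drifts away), which would make every recovery property vacuous.
Residual SDs are deliberately below the cross-sectional baseline SDs of a
real registry, because those include between-subject spread that the class
structure already carries.

Visit schedules are uniform over follow-up plus a mandatory time-0 visit —
the least-informative choice given only counts and spans.  Consequences:
real registries measure newly diagnosed patients more densely in the first
months, so early-window class assignment is *easier* here than in real
data; the generator's covariates influence the hazard only through class
membership unless `covariate_effects` is set, so covariate HRs in Cox fits
on default data estimate proxies of class, not causal effects.  Event
times are exponential (constant hazard per class); real HHF hazards are
time-varying.  Passing recovery tests on this generator demonstrates
correctness of the estimation machinery under the stated structure, not
performance on real registries.

The `true_class` column in `subjects.csv` is oracle-only ground truth for
tests; no pipeline stage reads it.  `events.csv` records `event_weeks`
from the *first specimen date* (the anchor that remains observable
downstream); the cohort stage converts to weeks from the DDD and treats
only events strictly after the DDD as events.

## Pipeline analyses

* **Primary**: cohort → selection (or fixed shape/K) → KM per class,
  omnibus and pairwise log-rank, covariate-adjusted Cox with class
  indicators.
* **Baseline shift**: drop measurements before the shift (default 50
  weeks), re-zero, refit the selected model, match classes by mean-curve
  assignment, tabulate flows; Cox contrasts subjects newly flowing into a
  target class against subjects originally in it (time origin unchanged,
  adjusted and unadjusted).  Subjects left with < 2 measurements are
  excluded and counted.
* **Re-seeding**: rebuild the cohort under a second imputation seed, refit,
  match, report the retained-membership fraction and per-class log-rank
  between the two assignments.
* **Predictive validation**: 80/20 subject split; LCGA and Cox fitted on
  training only; held-out class retention against a full-data fit; for each
  cumulative window [0, w·50] weeks, class membership is re-predicted from
  the truncated trajectories while the Cox coefficients stay fixed, and
  Harrell's C is computed on the full validation follow-up.  Subjects with
  no measurement inside the first window are excluded once.  A no-class
  Cox model provides the reference concordance.

With ~8 validation events at n = 2500, a single seed's concordance curve is
a step function of a handful of events; the rising-information effect is
therefore assessed on the *seed-averaged* curve (first window vs last
window over 10 seeds), and the class-vs-no-class comparison over 20 seeds.

## Problem sizes and numerical settings

Tests and the acceptance script run at n = 2000–2500 subjects with reduced
multi-start counts (5–10 starts) — sizes at which every assessed property
is statistically identifiable while the whole suite completes in a few
minutes.  Tolerances: EM relative log-likelihood 1e-6 (1e-10 in
equivalence tests); Cox Newton 1e-9 relative; oracle comparisons at the
precision stated in each test.  Determinism: every stochastic step
(generation, imputation, EM starts, splits, CV folds) is a pure function
of an explicit integer seed.

## Known limitations

No random effects (by design — LCGA, not growth mixture modelling); no
covariate-dependent class membership; no time-varying covariates, competing
risks or penalized Cox; the generator does not model institutional
missingness of event records, treatment effects on trajectories, or
calendar-time effects.  BIC magnitudes are not comparable across packages
or datasets because the basis scaling and likelihood constants differ.
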