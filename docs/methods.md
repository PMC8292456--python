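# Methods

## The estimation problem

Observational PD cohorts follow patients for only 5–7 years, yet the
dynamics of CSF and serum biomarkers play out over decades around the
onset of motor symptoms. `pdtraj` reconstructs a marker's long-term
trajectory from short per-subject follow-up using a rate-versus-level
argument: if a marker's population dynamics are governed by an autonomous
first-order ODE,

    dX/dt = f(X),

then the function f can be estimated cross-sectionally — each subject
contributes one (baseline level, annual change rate) point — and the
long-term trajectory is obtained by integrating f from a single anchored
level. No parametric shape (exponential, sigmoid, …) is assumed for the
trajectory itself; the shape emerges from the fitted f.

The pipeline has five stages.

### 1. Cohort filters

Applied in a fixed order, each exclusion logged with a reason code:

1. **Minimum measurements** — a subject-marker series needs ≥ 2 valid
   measurements (a slope requires two points).
2. **Hemoglobin screen** — CSF α-synuclein samples with hemoglobin
   ≥ 200 ng/mL are dropped (blood contamination inflates α-synuclein;
   the rule is sample-level and α-synuclein-specific). Samples with
   missing hemoglobin are retained with a warning (configurable). If the
   screen leaves a series with fewer than 2 points, the series is dropped
   in the same stage, which keeps the full chain idempotent.
3. **Baseline outliers** — a subject is excluded for a marker if its
   *baseline* value lies strictly more than 3 interquartile ranges below
   Q1 or above Q3 of that marker's baseline distribution. Quartiles use
   linear interpolation between order statistics (configurable); the rule
   is applied per marker and needs ≥ 4 baseline values.
4. **Cognitive outliers** — a subject is excluded for a cognitive score
   if *any* of its visits lies strictly beyond the group's baseline mean
   ± 4 sample SD for that score. Screening all visits (not only baseline)
   is deliberate: with small cohorts the baseline sample SD is inflated by
   the outlier itself, and the largest achievable baseline z-score is
   (n−1)/√n (&lt; 4 for n &lt; 18), so a baseline-only rule could never fire
   on a small group; longitudinal values are screened against the baseline
   reference instead.

Boundary conventions (all strict, "more than"/"beyond"/"<"): hemoglobin
exactly 200 is excluded; a value exactly on the 3×IQR fence is retained; a
score exactly at 4 SD is retained. Stratification: PD subjects are split
by baseline cognition (MoCA > 25 → PDCU, else PDCI) and by baseline CSF
amyloid-β 1-42 (strictly below 683.45 pg/mL → low; the cut-off value
itself falls in the high group). Missing covariates make a subject
unclassifiable for that stratification only.

### 2. Per-subject kinetics

Ordinary least squares of marker value on time for every subject-marker
series. For PD subjects time is disease duration (years since
self-declared motor onset), so the intercept extrapolates the level back
to onset; for controls time runs from the baseline visit. The slope is
the subject's annual change rate (marker units/year). Series with zero
time variance are excluded (`zero_time_variance`). The group **anchor**
is the arithmetic mean of per-subject onset levels (median available via
config); fits are unweighted by series length.

### 3. Rate-versus-level spline

The population rate function f is a restricted (natural) cubic spline
regression of per-subject rate on per-subject baseline level. Knots sit
at the 5/35/65/95 percentiles of the baseline levels; when the fitting
sample has fewer than 100 subjects, 3 knots at 5/50/95 are used instead.
Percentiles use linear interpolation (configurable); coincident 4-knot
placements fall back to 3 knots, and still-coincident knots are an error.
The basis is the truncated-power natural-spline construction (b₁(x)=x and
K−2 restricted cubic terms), twice continuously differentiable and exactly
linear outside the boundary knots. Nonlinear columns are divided by
(t_K−t₁)² by default purely for conditioning; fitted values are invariant
to that rescaling (same column span), and both parameterizations are
exposed and tested for identical predictions. Rank-deficient designs are
rejected with the condition number in the error message.

**Known bias — pairing choice.** The OLS slope is the *average* rate over
the subject's visit span, but it is paired with the level at the span's
*start* (the first observed value, `baseline_stat="first"`, the default,
matching the convention of regressing annual change on baseline values).
On curved trajectories this attenuates the recovered rate function: on the
benchmark with true f(X) = −0.08(X−600) and six annual visits the fitted
slope is ≈ −0.065. The zero of f (the plateau) is unaffected — the fitted
function remains a line through the true root. Setting
`baseline_stat="mean"` pairs the averaged rate with the span's mean level,
which is unbiased for linear f; it is offered as a config alternative
rather than the default to keep the default faithful to the
baseline-value convention.

### 4. Trajectory integration

The ODE dX/dt = f(X) is integrated with the modified Euler method. "Modified
Euler" names two second-order schemes; the Heun predictor–corrector

    x' = x + (h/2) [ f(x) + f(x + h·f(x)) ]

is the default, with the explicit midpoint rule available via config —
the recovery properties hold for either. The step is h = 0.01 years by
default; a convergence self-check (h vs h/2 maximum difference) is logged
for every integrated trajectory. Integration runs forward from the anchor
(t = 0, the group mean onset level) to +30 years and backward with step
−h to −5 years; the level at t = 0 equals the anchor exactly.

**Extrapolation corridor.** The natural-spline linear tails are not
trusted far outside the observed baseline range: once the state leaves
`fit_range` widened by 25% of its width on each side, the rate is held at
the corridor-edge value and a diagnostic is recorded. This prevents a
steep extrapolated tail from driving unphysical blow-up. Negative levels
are mathematically allowed but logged. Integration aborts with an event
log if |X| exceeds 10⁶ × the anchor scale.

**Controls.** Controls have no onset, so the control model is integrated
on the age axis from the anchor (median control baseline age, control
baseline mean level) and re-indexed onto the duration axis with
`duration = age − median PD age at onset`. Controls are integrated with
the identical machinery as PD (not drawn as flat lines), so a genuinely
stable control marker produces a near-flat curve by estimation, not by
construction.

### 5. Summaries

Z-scores standardize every trajectory against the control group's
*baseline* mean and sample SD per marker (not longitudinal moments).
Reported per marker and stratum: the 30-year percent change
100·(x(30)−x(0))/x(0); the zeros of f within `fit_range` (located by a
2001-point sign scan refined by Brent bisection to |f| < 1e−9, each
labelled stable if f′ < 0); the earliest PD-versus-control crossing time
and the z = 0 crossing time (first sign change on the grid, refined by
linear interpolation). Markers whose control baseline SD is not positive
get no z-scores (logged).

## Synthetic cohort generator

The generator emulates the structure of the cohort the method targets so
that every stage has a recoverable ground truth: ~396 PD and ~182 control
subjects; age at onset ~ N(60, 10²) truncated to [30, 90]; baseline
disease duration ~ N(2.0, 2.0²) truncated at 0; visits at baseline and
6–72 months (no 42-month visit) with independent per-visit dropout
(default 10%, baseline always kept) and optional unscheduled visits;
five biofluid markers and three cognitive scores.

Each marker follows a closed-form trajectory family — exponential
approach to a plateau (amyloid, α-synuclein, tau species, cognitive
scores), logistic growth (NfL) or constant (controls) — with
between-subject heterogeneity entering through the onset level only
(one population-level f(X), matching the method's own assumption; default
onset-level SDs echo the cross-sectional SDs of the emulated cohort).
Measurement noise is additive Gaussian on the measurement scale with
per-marker SD. Contaminants are planted and recorded in a hidden truth
table: a configurable fraction of α-synuclein samples receives hemoglobin
≥ 200 ng/mL, and configurable fractions of subjects receive an extreme
baseline value (≈ 15× the true level) or an extreme cognitive score
(+60). The same configuration and seed always produce byte-identical
tables.

What the generator does **not** emulate: assay batch effects, detection
limits/censoring, the real visit-compliance pattern, rate heterogeneity
between subjects, and coupling between markers. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to those real-data features.

`recovery_benchmark_config()` freezes the end-to-end benchmark: one
marker with truth dX/dt = −0.08(X−600), mean onset level 1000,
between-subject onset SD 380 (≈ 38% relative spread — wide enough that
observed baselines straddle the plateau, without which the rate root
would be unidentifiable from data), noise SD 20, six annual visits,
n = 400 PD. Under these conditions the pipeline's trajectory RMSE against
truth over t ∈ [0, 20] is a few percent of the 400-unit dynamic range and
the recovered stable root lies within a few units of 600; the anchor
(mean of 400 extrapolated onset levels) carries ≈ 19 units of sampling
noise, which dominates the error budget.

## Numerical choices and degenerate inputs

- Quantile convention everywhere: linear interpolation between order
  statistics; sample SDs use ddof = 1.
- OLS via closed-form normal equations per subject; spline fits via
  `numpy.linalg.lstsq` after a rank check.
- Root refinement: Brent's method, xtol 1e−12; roots closer than 10 grid
  cells are deduplicated; a rate curve whose maximum |f| ≤ 1e−9 has no
  isolated roots and returns an empty set.
- Crossing times: first sign change on the common grid, linearly
  interpolated; identical curves cross nowhere; an exact zero at a grid
  point counts at that time.
- Empty inputs pass through filters with a warning; strata too small to
  fit (fewer than 5 subjects or fewer than 10 distinct baseline levels)
  are skipped and logged, never silently imputed.
- The run manifest records a config hash, seed, per-stage row counts,
  version and a wall-clock timestamp; every other output is byte-stable
  under a fixed config and seed.

## Problem sizes

Default analyses integrate with h = 0.01 years over [−5, 30]
(3501 grid points per trajectory) and export on a 0.25-year reporting
grid. The test suite and the acceptance script use cohorts of 80–400
subjects per group with a single marker for recovery checks and the
full 8-marker default cohort for pipeline-level checks.

## Limitations

- The method assumes one population-level f(X); subgroup heterogeneity is
  addressed only through the predefined strata.
- Extrapolation to ±30 years rests on levels observed over ≤ ~8 years of
  disease duration; the corridor clamp makes far extrapolation
  conservative rather than correct.
- No uncertainty quantification: the spline fit and the integrated
  trajectory carry no confidence bands.
- The first-value pairing bias described above attenuates rate constants
  on strongly curved trajectories.
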