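# Methods

## The trajectory model

The package models the conditional distribution of post-operative BMI
through a small set of percentile curves. For quantile level τ,

Q_τ(BMI | b₀, a, t) = β₀ + β₁(b₀−50) + β₂(a−50) + β₃d + β₄d² + β₅d³
+ β₆(b₀−50)d + β₇(a−50)d, with d = t − 6,

where b₀ is preoperative BMI (kg/m²), a age (years) at the initial
preoperative visit, and t months after surgery. The cubic time polynomial
lets the curve fall steeply, reach a nadir and partially regain; the
BMI×time and age×time interactions let the shape vary with the patient.
The centered parameterization (deviations from BMI 50, age 50, month 6) is
canonical internally because the packaged published coefficients are
expressed that way; `uncentered_to_centered` converts coefficients written
against raw covariates. At the centering point every non-intercept term
vanishes, so the prediction equals β₀ exactly — a useful identity that the
tests exploit.

The packaged default coefficient set carries three percentiles
(τ = 0.25, 0.50, 0.75) with validity ranges b₀ ∈ [35, 95] kg/m²,
a ∈ [18, 74] y, t ∈ [0, 36] months. Queries outside the ranges raise by
default; an explicit flag downgrades to a warning, because the cubic is
unsafe to extrapolate. Time zero is the date of surgery and negative times
are always rejected. Calendar dates convert to fractional months with the
fixed divisor 30.4375 days/month, keeping conversions deterministic.

With these coefficients the three curves do not cross anywhere on the
study grid, predictions increase strictly in baseline BMI and
non-strictly in age (the effective slopes β₁+β₆d and β₂+β₇d stay positive
over d ∈ [−6, 30]), and the median curve for the reference patient reaches
its nadir between months 12 and 24 before regaining — all verified by the
test suite rather than assumed.

Display rounding in lookup tables is round-half-even to one decimal, a
presentation convention of this package; full-precision values are always
retained alongside. Note that the printed lookup tables circulating for
this model differ from direct formula evaluation by ≈0.1–0.2 kg/m²
(they were evidently built from unrounded coefficients); this package
reproduces the formulas, not those printed cells, and reports the
difference as a diagnostic only.

## Fitting by check-loss minimization

`fit_quantile` minimizes the mean check (pinball) loss
ρ_τ(r) = r·(τ − 1{r<0}) of the residuals over the centered 8-column basis.
This is a linear program. Two formulations are used:

- **n ≤ 2000 rows:** the primal split-residual LP
  (min τ·Σu + (1−τ)·Σv s.t. Xβ + u − v = y, u,v ≥ 0), followed by a second
  LP that minimizes the intercept subject to the stage-1 optimum. On flat
  optima (e.g. even-sized samples in an intercept-only design) this pins
  the solution to the *lowest minimizer*, so the intercept-only fit equals
  the classical lower sample quantile, bit-stably.
- **n > 2000 rows:** the standard dual LP
  (max yᵀα s.t. Xᵀα = 0, α ∈ [−(1−τ)w, τw]), whose equality-constraint
  marginals are the coefficients. The duality gap between the achieved
  primal loss and the dual objective certifies optimality (tolerance
  1e−7 relative); a gap beyond it raises a convergence error rather than
  returning an uncertified fit. For continuous responses the optimum is
  almost surely unique at these sizes, so no tie-break is needed; a
  degenerate large problem would return an optimal vertex without the
  lowest-intercept guarantee.

Both paths run HiGHS through `scipy.optimize.linprog` and are
deterministic given fixed inputs. Rank-deficient designs raise
immediately. Repeated measures are pooled as independent observations in
the loss — marginal conditional quantiles are the estimand, and the
estimating equations remain unbiased under within-patient dependence;
per-patient inverse-frequency weighting is available but off by default.

No standard errors or confidence bands are produced; quantile crossing of
fitted curves is flagged downstream (the simulator refuses a crossing
truth model) but never repaired.

### Covariate screening

Candidate covariates (baseline BMI, age, sex, diabetes) are screened
against two patient-level outcomes: %EWL at the six-month visit and nadir
BMI. The standardized effect is the signed partial correlation from an OLS
of the outcome on the covariate adjusting for baseline BMI and age
(self-adjustment skipped) — the conventional effect-size scale on which
0.1 is the small/moderate boundary, and one that is insensitive to the
outcome's marginal variance being dominated by other covariates. A
covariate is retained when |effect| ≥ threshold (default 0.1) on both
outcomes with a consistent direction of association with weight loss; the
nadir-BMI effect sign is flipped for that comparison because more loss
means a higher %EWL but a *lower* nadir BMI. Under the default synthetic
conditions baseline BMI is retained overwhelmingly, sex and diabetes
(null covariates in the generator) never are, and age shows a
directionally consistent, statistically significant but weak signal
(partial r ≈ 0.08): the published age coefficients are small relative to
the within-patient quantile spread, so age clears the default threshold
only in cohorts with a stronger age effect than the packaged model
implies. Diabetes and sex are screened but never enter the trajectory
model.

### Comparing fits

`compare_fits` evaluates two fitted coefficient sets on a reference
profile (baseline BMI 50, age 50, t ∈ [0, 36] by 0.5) and reports per-τ
maximum and mean absolute BMI differences. Fitting two independent
synthetic cohorts of 2600 and 380 patients from the same truth yields a
maximum discrepancy of ≈1.2 kg/m² (tested against a 1.5 kg/m² bound) —
the sampling-noise scale against which a real primary-vs-validation
comparison should be judged.

## The synthetic cohort generator

The generator is first-class, tested code; it defines the conditions under
which the fitting machinery is validated.

**Demographics.** Age ~ Normal(45.8, 11.2²) truncated to [18, 74];
baseline BMI ~ Normal(49.5, 8.7²) truncated to [35, 95]; 81% female.
Sampling is by rejection, reproducible from the seed. Height is not part
of the modelled data-generating story but is needed to derive weights from
BMIs: Normal(1.66, 0.09²) m truncated to [1.4, 2.1], a package choice of
plausible adult stature. Diabetes is a Bernoulli(0.33) *null* covariate —
roughly the prevalence seen in bariatric programs — present only so the
screening step has something to correctly reject.

**Visit process.** Nominal visits at 1 wk, 2 wk, 2, 5, 8, 12 months, then
every 6 months to 36. Each visit time is jittered uniformly ±10 days
(converted at 30.4375 d/month) to mimic real scheduling irregularity and
exercise nearest-visit logic; jittered times are re-sorted and exact ties
dropped.

**Conditional quantiles.** Each measurement's BMI is F⁻¹(u) for the
conditional distribution implied by the truth coefficient set: piecewise
linear in τ between the (τ, BMI) knots for u within the knot range, and
Gaussian tails outside, with σ = (outer-knot gap)/(z_{τmax} − z_{τmin})
anchored *at the outer knots* so that F⁻¹(τ_k) reproduces the k-th
percentile curve exactly even when the published quantiles are asymmetric.
Only three quantiles are published, so the tails are invented; ranks are
clipped to (0.001, 0.999) to keep the invented tails from dominating. A
crossing truth model aborts generation with an error.

**Within-patient persistence.** Clinically, a patient tends to ride one
percentile track. Ranks therefore come from a Gaussian copula:
u_visit = Φ(√w·Z_patient + √(1−w)·ε_visit), with persistence weight
w = 0.8 by default. Marginally each u_visit is *exactly* Uniform(0,1) —
so the generator's conditional quantiles equal the truth model's
predictions regardless of w — while w = 1 collapses to a single shared
rank and w = 0 to independent visits. (A convex combination of uniforms,
the obvious alternative, is not marginally uniform and would bias the
outer conditional quantiles by ≈0.45 kg/m² at w = 0.8; the copula
construction avoids that distortion entirely.) The latent Z is drawn
independently of the covariates.

**Attrition.** Follow-up ends at a censoring time drawn from a
piecewise-constant hazard; visits after it are removed, and every patient
keeps at least the first visit. The hazard rates are solved by 1-D root
finding so that the *expected empirical* retention — the probability that
some retained, jittered visit time exceeds the horizon — equals the
targets 88%/77%/53% beyond 6/12/24 months. The calibration integrates
over the censoring density against the exact retention indicator implied
by the discrete schedule and jitter; hazard-piece boundaries sit just past
the first visit that certainly exceeds each horizon, which makes the
calibration triangular (each rate solvable given the previous ones).
Naive interval-ratio calibration (0.88, 0.875, 0.688 conditional survival
per interval) ignores the schedule and would measure ≈84% beyond 6 months
on generated data; the ratios are kept only as a diagnostic identity.

**What the generator does not emulate.** Preoperative (negative-time)
measurements; diabetes or sex effects on trajectories; informative
dropout (censoring is independent of weight loss); EHR-style data errors
(unit typos, duplicated charts) beyond what the cleaning tests inject
synthetically; secular drift across surgery eras. Passing recovery tests
therefore shows the estimator is correct under clean, correctly-specified
conditions — not that the model is correct for any particular real
cohort.

## Cleaning

Cleaning rules are package inventions, deliberately configurable, not
facts about any study: BMI outside [12, 100] kg/m² is implausible;
adjacent measurements changing faster than 1.5 kg/m²/week are
inconsistent (the offender whose removal most reduces the total violation
is deleted, earliest on ties, iterating to a fixed point); equal weights
within 0.25 months collapse to the earlier record. The operation is
idempotent and every removal is logged with the single rule that fired.
Note that the default simulator with visit-level rank noise can
legitimately trip the rate rule between the two closely spaced early
visits — realistic, and a reminder that the thresholds interact with
visit spacing.

## Outcomes and tracking

%EWL uses the BMI-25 reference weight (25·height²), the dominant
bariatric convention, making %EWL an affine function of current weight
anchored at 0 (baseline) and 100 (reference). The six-month outcome takes
the measurement nearest 6.0 months within ±1.5 months (nearest, then
earlier on ties) — the window excludes the 8-month visit by construction;
absence is a missing value, not an error. The nadir is the minimum
observed BMI (earliest on ties). Band classification against the three
percentile curves is half-open upward: a BMI exactly on a percentile
belongs to the band above it. Measurements beyond the model's time range
are classified by extrapolation but flagged.

## Problem sizes and numerical choices

The validation suite uses cohorts of 380–10000 patients: 4000 for
coefficient recovery (≈31k measurements; recovered baseline-BMI effects
within ±0.015 of truth, asserted at ±0.03), 5000 single-visit patients for
conditional-quantile fidelity (±0.3 kg/m² at the reference point), 10000
for retention calibration (±2 points), and 2600/380 for the two-cohort
comparison. LP fits take ≈1 s per quantile at 31k rows via the dual path.
Tie-break slack is 1e−11 relative; duality-gap certification 1e−7;
solver-oracle agreement is asserted at 1e−6 on intercept-only problems
against a brute-force scan of the check loss over sample values.
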