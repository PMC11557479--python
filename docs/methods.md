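# Methods

This note documents the statistical procedures the package implements, the
choices made where the published methodology leaves room, and what the
synthetic cohorts do and do not establish.

## Demographic adjustment

Per measure, an ordinary-least-squares fit of the raw score on a female
indicator (male = reference, coded 0), age and education in years. The
correction uses the **full-model** coefficients of the predictors whose
two-sided p-value is below alpha (default 0.05); non-significant terms are
dropped from the correction but the retained coefficients are *not* refit.
This convention is pinned by the published tables themselves: the printed
correction constants equal the full-model betas to the printed precision.

The adjusted score is `raw − Σ b_j (x_j − c_j)` with centering constants
equal to the fitting sample's means (the published norms use 61.334 years
of age and 11.316 years of education). Adjusted scores are deliberately
not clipped to the measure bounds: an adjusted accuracy above the maximum
is meaningful relative to the normative distribution. Demographics outside
the normative ranges (age 50–80, education 2–30) trigger a logged
extrapolation warning, not an error.

Optional extra covariates (e.g. an "assistance received" flag) enter the
regression but never the correction; they exist to verify that such
nuisance factors do not change the retained-predictor sets.

Degenerate inputs: a zero-variance response returns an explicit null model
(all coefficients 0, nothing significant) rather than propagating 0/0
t-statistics; a single-sex cohort or otherwise rank-deficient design is an
error.

## Tolerance limits

One-sided non-parametric tolerance bounds on the worst `q` fraction of the
population (default q = 0.05) at confidence γ = 0.95, computed from exact
binomial tail sums built incrementally from `(1−q)^n` in log space — exact
for any practical n, no normal approximation:

* outer rank = largest `r ≥ 1` with `P[Bin(n, q) ≥ r] ≥ γ`;
* inner rank = smallest `r` with `P[Bin(n, q) ≤ r−1] ≥ γ`.

The inequality convention above reproduces the published ranks (10, 24) at
n = 323 and is used throughout. The outer limit is infeasible below
n = 59 (`1 − 0.95^58 < 0.95`); the error names the minimal n. Values at
the ranks are reported as the order statistics in worst-to-best order
(ascending for accuracy, descending for times); ties straddling a rank are
reported as-is, with no interpolation.

Classification of an adjusted score: **abnormal** at or beyond the outer
limit (the cut-off), **normal** at or beyond the inner limit, **borderline**
strictly between. Including the inner-limit value in "normal" follows the
published handling of the attention subdomain, where reaching the inner
score is explicitly normal performance.

## Equivalent Scores

Five ordinal levels with boundary ranks fixed by n alone: the outer
tolerance rank, `round_half_up(n·Φ(−1.22))`, `round_half_up(n·Φ(−0.61))`,
and `floor(n/2)`; level 4 is everything better than the median. The two
interior z-constants reproduce the published cumulative frequencies
(10, 36, 88, 161, 323) at n = 323 exactly; they were inferred from those
tables (the underlying interval criteria are not published as formulas) and
are flagged as such here. Rank rounding is half-up. Boundary values belong
to the worse level (ES 0 is "≤ cut-off" for accuracy, "≥ cut-off" for
times), which makes ES 0 membership identical to the abnormal
classification.

**Ceiling rule.** A table is not emitted (tolerance limits only) when three
or more consecutive boundary order statistics are equal. A single tied
boundary pair is allowed: the published math-accuracy table has equal ES2/
ES3 boundaries at the measure maximum yet is printed, while attention —
where everything from the ES1 boundary up sits at the maximum — is reported
with limits only. The three-in-a-row rule separates exactly these two
cases and is the package's operationalization of "most individuals reached
the inner tolerance score".

## Published norms

The constants of the Italian SATURN normative study (n = 323) are bundled:
per-measure regression summaries and correction formulas, tolerance-limit
values (total accuracy 16.56/18.57; total time 832.83 s/706.56 s), ES
boundaries, and the printed correction grids. The grids are lookup-only:
the representative demographics behind each printed cell are not
recoverable, so the package does not attempt to regenerate them (its own
grid builder takes explicit representatives, defaulting to fitting-sample
cell means, falling back to band midpoints for empty cells).
`load_published_norms()` revalidates the set on every load — the regression
constants must re-render every published formula string and the ES
boundaries must match the tolerance limits and the rank scheme — so silent
transcription drift fails loudly.

Task-level aggregation: 19 tasks in seven subdomains; a subdomain score is
the mean over its tasks, totals are sums over all 19. Only the subdomain
maxima (2, 1, 1, 5, 1.5, 1, 5/3) and the total maximum of 29 are fixed by
the published scoring; the within-subdomain point split is a configurable
default. The executive maximum is stored as 5/3 exactly so that
`Σ max × task-count = 29` holds as an identity.

## Synthetic cohorts

The generator reproduces the published design: 18 strata (sex × three age
bands × three education bands) with the published counts totalling 323
(180 F/143 M), integer ages uniform within band, education uniform within
band (<9 → 2–8; 9–13 → 9–13; >13 → 14–19, a compact default below the
observed maximum of 30). An assistance flag is assigned independently at
the published rate 86/323.

Measures follow `latent = intercept + b_sex·female + b_age·(age − 61.334) +
b_educ·(educ − 11.316) + ε` with per-measure noise families:

* **gaussian-clipped** (accuracies): Gaussian residual clipped to the score
  bounds; clipping produces realistic ceiling mass on bounded scores and a
  small attenuation of fitted coefficients (≈5% for total accuracy).
* **discretized**: additionally snaps to the score grid (step configurable).
* **lognormal** (times): multiplicative mean-one lognormal noise on the
  linear predictor, so values are positive and right-skewed while
  `E[value | demographics]` equals the linear predictor exactly — OLS
  recovers second-scale coefficients without transformation bias. The log
  scale is set from the target coefficient of variation.

Default intercepts and effect sizes are the published means and regression
coefficients; residual scales are back-solved so marginal SDs approximate
the published descriptives (total accuracy residual SD 3.1 against a
marginal 3.25). These are calibration targets, not ground truth: the
published residual variances and between-measure correlations are not
recoverable, measures are generated independently given demographics, and
the continuous accuracy families do not reproduce the extreme discreteness
of the real attention distribution (synthetic attention tables typically do
not ceiling-degrade; the degradation logic is exercised with constructed
tied data in the tests). Passing tests on synthetic cohorts therefore
validate the *procedures* — rank computations, partition conservation,
coefficient recovery, type-I control — not distributional fidelity to the
real cohort.

Randomness: one root seed; each measure (and the demographics and the
assistance flag) draws from a stable CRC-derived substream, so adding a
measure never perturbs the others and cohorts are bit-reproducible.

## Pipeline and reports

`run_study` executes, per measure on its complete cases: descriptives
(sample SD, midpoint median), the regression, adjusted scores, tolerance
limits, the ES table and the correction grid, isolating per-measure
failures (ceiling, undersized subsets) as recorded skip reasons. Pearson
correlations (two-sided p) are computed between adjusted catalog measures
and any pre-adjusted external instrument columns (MMSE/MoCA arrive already
adjusted by their own norms). Reports serialize to JSON at full precision;
display tables round half-up at a configurable number of decimals
(default 2). The pipeline is deterministic; all randomness lives in the
generator.

## Problem sizes

The validation studies use the stratified design at k = 1 (n = 323) for
structural checks, k = 100 (n = 32,300) for coefficient recovery (±0.01
on the education effect), 200 replicates at n = 323 for type-I control,
and exhaustive rank/oracle agreement for all feasible n ≤ 2000.
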