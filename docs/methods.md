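# Methods

## The compositional model

A subject's 24-hour day is a 4-part composition `x = (sleep, SB, LPA, MVPA)`
closed to 1440 minutes. All inference happens in Aitchison geometry: the
centred logratio (clr) maps `x` to `ln(x_j / gm(x))`, and pivot (orthogonal
logratio) coordinates give an orthonormal basis of the (D−1)-dimensional
quotient space. With part order `(x_1, …, x_D)` the k-th pivot coordinate is

```
z_k = sqrt((D−k)/(D−k+1)) · ln( x_k / gm(x_{k+1}, …, x_D) )
```

so `z_1 = sqrt(D/(D−1)) · clr_1`. For each behaviour part in turn, the
basis is rebuilt with that part first and only `z_1` is modelled:

```
z_1 = X β + ε,      ε ~ N(0, σ²)
```

by OLS on the covariate design (intercept, age, BMI z-score, summer season,
pubertal status, two parental-education dummies with "secondary or less" as
reference, walkability; perceived-safety optional), fitted separately for
girls and boys. The covariate coefficient θ is rescaled to the clr scale
(`b = sqrt((D−1)/D)·θ`) and reported as `100·(exp(b) − 1)` — the percent
difference in the time share of that part, per unit covariate, relative to
the whole composition. Fitting each part's model on the same design makes
the four clr coefficients of any covariate sum to zero exactly (OLS is
linear in the response and the clr components sum to zero identically), so
each reported row satisfies the product-to-one constraint
`∏_j (1 + p_j/100) = 1` before rounding. This is tested at 1e−10.

**Confidence intervals.** Wald intervals with t quantiles (df = n − p) on
the coordinate scale, transformed through the same monotone map
(endpoint transformation, not the delta method). This choice produces the
asymmetric percent-scale intervals characteristic of exponentiated
estimates; the intervals are exact images of the coordinate-scale ones.

**Linear comparison models.** Each behaviour in hours/day (closed to 24) is
regressed on the identical design. Because the outcomes sum to the constant
24, per-covariate coefficients sum to zero and intercepts to 24; both are
asserted at 1e−9.

**Compositional means** are closed per-part geometric means (the clr of the
mean equals the mean of the clr vectors). Descriptive comparisons use Welch
two-sample t tests for continuous variables and chi-squared tests without
continuity correction for categorical ones. Residual normality is screened
with the D'Agostino–Pearson omnibus test at the 5% level; an all-zero
residual vector (exact fit) is flagged as degenerate rather than tested.

## Accelerometer processing

Per-minute counts (CPM) are processed as:

1. **Non-wear**: maximal runs of zero counts spanning ≥ 60 min, allowing at
   most two interruption episodes of ≤ 2 consecutive minutes, each minute
   < 100 CPM; a window must start and end on zeros. Any minute ≥ 100 CPM
   breaks the window.
2. **Sleep**: per night, among non-wear gaps starting between 18:00 and
   03:00 and ending (refit) between 03:00 and 12:00 the next morning, the
   longest is sleep (ties: earliest start), credited to the night's
   starting day and excluded from daytime non-wear. The evening/morning
   window bounds are an operationalization of "removed at night, refitted
   in the morning"; they are configuration-level constants, not published
   facts. Days with no detectable overnight gap borrow the subject's mean
   sleep over other days; with no such day, the day is dropped.
3. **Intensity**: SB < 100 CPM, LPA 100–2295 CPM, MVPA ≥ 2296 CPM, applied
   to worn minutes only. Boundaries are exact and tested.
4. **Validity**: a day is valid with ≥ 600 worn minutes; a subject with
   ≥ 4 valid days including ≥ 1 valid weekend day.
5. **Weighting and closure**: behaviour means are (5·weekday mean +
   2·weekend mean)/7, zero-replaced (multiplicative replacement, floor
   1 min) and closed to 1440 min. Validity filtering precedes weighting.

Epoch length is fixed at 60 s, matching the count-based device generation
this pipeline targets. Day boundaries are calendar midnights.

## Walkability score

Six indicators (3+-way intersections, land-use mix, park count, low-traffic
street length, park-area ratio, social-disorder segments) are z-scored
(denominator n−1) and decomposed by eigendecomposition of their correlation
matrix — correlation, not covariance, because the indicators have
incommensurate units. The score is the projection on the first eigenvector,
re-standardized to mean 0 / sd 1, with the sign anchored so the
intersection-density loading is positive. The variance share is λ₁/6. A
scree rule (largest consecutive eigenvalue drop) is evaluated and warns if
it does not retain exactly one component, but the pipeline always uses one
component: the score is defined as a one-factor summary. Score–indicator
associations are reported as Spearman correlations.

## Synthetic cohort generator

The generator defines the validation conditions; its defaults are fixed
once and shared by tests and the acceptance script.

* **Covariates** (independent draws): age ~ N(9.6, 0.9²) truncated to
  [8, 11] years (recruitment at ages 8–10 with measurement up to about a
  year later; a [8, 10] truncation cannot carry an sd of 0.9), P(girl)
  = 0.46, BMI z ~ N(1.0, 1.3²), P(puberty initiated) = 0.23, P(summer
  measurement) = 0.46, parental education (0.22, 0.25, 0.53) over
  secondary/technical/university, P(perceived unsafe) = 0.25 (a plausible
  minority response; no target moment exists for it). Real cohorts
  correlate age with puberty and season with activity; the generator does
  not, so passing recovery tests demonstrates estimator correctness, not
  robustness to covariate dependence.
* **Indicators**: `indicator_i = l_i·latent + sqrt(1−l_i²)·noise`, pushed
  through monotone marginal transforms (rounded counts, clipped ratios).
  Loadings are the target Spearman profile (0.86, 0.82, 0.79, 0.71, 0.69,
  0.56 for low-traffic streets, intersections, parks, land-use mix,
  park-area, disorder) scaled by 1.081, calibrated once so the first-PC
  variance share is 0.70 ± 0.02 at n = 5,000 *after* the marginal
  transforms.
* **Compositions**: Gaussian noise on pivot coordinates (logistic-normal)
  around `clr(base) + Σ_c x_c·b_c`, base (10, 6, 7, 0.6) h, with
  per-covariate clr effect vectors each summing to zero. Default effects
  are realistic table-scale magnitudes for this population; the walkability
  vector is (−2.73, −4.14, −2.69)% on sleep/SB/LPA with MVPA balancing to
  +10.21%. Continuous covariates are centred at their generating means so
  the base composition is the reference-subject centre. The noise
  covariance is the projection `B diag(s²) Bᵀ` of independent per-part
  log-scale noise with s = (0.04, 0.208, 0.143, 0.376), calibrated once so
  *total* behaviour-hour sds land near (0.8, 1.1, 0.9, 0.3) h at n = 5,000
  (within ±20%; sleep floors at ~0.85 h because centring mixes the other
  parts' noise into it). A diagonal pivot-coordinate covariance cannot
  reproduce this sd profile — in the standard part order it forces LPA and
  MVPA to share a clr variance — which is why the covariance is specified
  through per-part sds instead.
* **Walkability ground truth**: the planted effect multiplies the latent
  factor, and the simulated cohort table carries the standardized latent as
  its walkability column, so recovery is exact in expectation. The
  PCA-estimated score computed from the indicators correlates ~0.96 with
  the latent; full-pipeline fits that regress on the estimated score are
  accordingly attenuated by roughly 4%, visible as slightly smaller effect
  estimates than the planted values.
* **Epoch traces**: 7 days starting on a Monday, each day's waking stretch
  interleaving SB/LPA/MVPA blocks (8/6/2 min) whose integer quotas match
  the subject's target composition, bracketed by light-activity minutes so
  sleep gaps are cleanly delimited; overnight removal at 22:00 ± 20 min
  with refit timed to the sleep target; sedentary minutes are zero with
  probability 0.3; one 60–90-min non-wear block is inserted on 20% of
  days. The trace starts mid-sleep at midnight and runs into the morning
  of day 8 so the last night has a refit. At these artifact rates the
  epochs → accelerometry → closure round trip keeps the mean absolute
  per-part error under 2% (tested at 200 subjects); with artifacts
  disabled, deterministic counts and an integer-minute target the round
  trip is exact.

All randomness flows from one master seed through per-stage
`SeedSequence` children, so each stage is independently reproducible and
repeated runs are bit-identical.

## Numerical conventions

* Closure tolerance 1e−9 relative; clr sum-to-zero and log-space identities
  1e−10 absolute; these sit well above double-precision round-off for
  1440-scale magnitudes.
* Zeros are replaced multiplicatively (floor 1 min on the 1440 scale)
  before any logratio; an all-zero vector is an error.
* Storage part order is (sleep, SB, LPA, MVPA); every result is invariant
  to it because the pivot basis is rebuilt per part (tested by permuting
  storage order).
* Rank-deficient designs raise an error naming a minimal set of collinear
  columns. Display rounding is 2 decimals; invariants are checked on
  unrounded values.

## Problem sizes

Test-suite simulations use cohorts of 40–5,000 subjects and 5–20 Monte
Carlo replicates; the acceptance script uses 100 replicates of n = 5,000.
These sizes put Monte Carlo error well inside the stated tolerances (the
per-cohort sd of the fitted MVPA percent difference is ≈ 0.5 points at
n = 5,000, so a 100-replicate mean has standard error ≈ 0.05).

## Limitations

* The pivot-coordinate normalization follows the standard construction; the
  product-to-one behaviour of published effect tables is consistent with
  it, but the original normalization is not printed anywhere to compare
  against symbol by symbol.
* Cross-sectional only: no longitudinal structure, mixed models or
  isotemporal-substitution matrices.
* The sleep rule equates overnight non-wear with sleep; awake non-wear at
  night is misclassified by construction, exactly as in count-based
  hip-worn protocols.
* The generator produces neither realistic circadian count profiles nor
  school-day structure; accelerometry tests validate the processing rules,
  not device realism.
* Safety is off by default in the fitted design (configurable); the
  descriptives and generator carry it either way.
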