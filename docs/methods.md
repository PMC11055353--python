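# Methods

This note documents the models, estimators and numerical choices behind
`sitfpca`, and what the synthetic-data experiments do and do not establish.

## Registration: the ordered-bout domain

Comparing movement *within sitting* across people requires a common domain.
Clock time does not work — a 20-minute bout at 9 am for one person has no
counterpart in another person's day.  Instead, each participant-day's valid
sitting bouts are ordered by length b = 1..B minutes and concatenated, so
minute m of the b-minute bout always occupies grid index t = b(b−1)/2 + m.
The grid has T(B) = B(B+1)/2 points (1830 at the default B = 60).  When a day
has several bouts of one length their minute-level VM vectors are averaged
(arithmetic mean of already-minute-aggregated counts); when it has none, the
whole length-b block is missing.  Missingness is therefore *block-structured*:
a block is present or absent atomically, and longer blocks are absent far
more often.  B is a parameter; nothing hard-codes 1830.

## Preprocessing

* **Waking windows.**  A sleep-log record is the overnight in-bed interval
  beginning on its date.  Day d's waking window runs from the end of the
  night finishing on d to the start of the night beginning on d.  Days
  missing either bound are dropped, not imputed; naps are unsupported.
* **Non-wear.**  A parameterized consecutive-zero detector on minute-level
  all-axis totals: maximal spans of ≥ 90 zero minutes that begin and end
  with zeros and contain ≤ 2 nonzero interior minutes.  These defaults
  mirror the headline parameters of the standard count-based non-wear rule;
  the full rule's upstream/downstream window checks are not implemented, and
  the detector is configurable so a stricter variant can be slotted in.
* **Bouts.**  Sitting events are merged into maximal sitting runs,
  intersected with waking windows, and split by non-wear (a split yields two
  bouts: the unit is uninterrupted sitting *within concurrent wear*).
  Per-second counts are summed per bout-relative minute; the trailing
  fraction is dropped below 30 s and otherwise rescaled by 60/f (an f = 30 s
  fraction is retained).  VM is computed from the minute totals, so
  VM ≥ each axis total by construction.  A bout whose count coverage has any
  gap is dropped with a warning.
* **Validity.**  A valid day has concurrent wear and 5–15 h of total daily
  sitting, evaluated *before* the ≤ 60-minute bout filter (the filters are
  applied in that order); participants need ≥ 1 valid day.  Timestamps are
  timezone-naive local time on a left-closed 1-second grid; a bout belongs
  to the calendar date of its waking window's start.

## The two-level model and its estimator

X_ij(t) = μ(t) + η_j(t) + Σ_k ξ_ik φ_k⁽¹⁾(t) + Σ_l ζ_ijl φ_l⁽²⁾(t) + ε_ij(t)
for subject i, day j, with ξ_ik ~ N(0, λ_k⁽¹⁾), ζ_ijl ~ N(0, λ_l⁽²⁾) and
ε ~ N(0, σ²) iid over grid points.

* **Mean and day shift.**  μ(t) is the pointwise mean of observed values;
  η_j(t) is the mean among rows with within-subject day order j minus μ,
  zeroed where day j is unobserved.  Day order is the only defensible
  cross-subject alignment of days — "day 1" of two subjects are not the same
  calendar event, so η is interpreted as an order-indexed shift.  Unsmoothed
  by default.
* **Covariances (method of moments).**  K_total(s,t) averages products of
  same-row residual pairs; K_between(s,t) products of pairs from different
  days of the same subject (whose shared term is only the subject-level
  process); K_within = K_total − K_between.  Under missingness each cell
  uses the pairs where both points are observed; cells with no pair are
  imputed by iterated local averaging and the imputed fraction is reported
  (error above 95%).
* **Noise variance.**  The raw diagonal of K_total carries signal + σ².  The
  signal diagonal is extrapolated from the two adjacent off-diagonal entries
  and σ² is the mean gap, floored at 0.  The diagonal is then replaced by
  the extrapolation, so the eigenanalysis sees the noise-free surface and
  K_between + K_within = K_total holds exactly by construction.
* **Eigenanalysis.**  The domain is an index set with unit spacing, so the
  rectangle rule makes the discrete eigendecomposition exact: matrix
  eigenvalues are functional eigenvalues; eigenvectors have unit discrete
  norm.  Negative and numerically zero eigenvalues (below 1e−12 of the top)
  are excluded.  Sign convention: each eigenfunction's largest-magnitude
  entry is positive.  Signs are arbitrary in any FPCA; downstream regression
  coefficients flip with them, so the convention is part of the model
  definition.
* **Surface smoothing and component selection.**  Raw moment surfaces carry
  a heavy sampling-noise tail: at n = 300 subjects × 4 days on T = 120, the
  spurious eigenvalues hold ~25% of the apparent total variance, which
  inflates the denominator of any explained-variance rule.  A Gaussian
  kernel smooth of both surfaces (default bandwidth 1.5 grid units, i.e.
  ~1% of T) suppresses that tail with negligible distortion of smooth
  low-frequency eigenfunctions; covariance smoothing before eigenanalysis is
  standard practice in functional data analysis.  Smoothing is off by
  default for fully observed fits, switched on automatically when any
  surface cell had no observed pair, and should be switched on explicitly
  when component counts are the quantity of interest.  Selection pools both
  levels' spectra, sorts by eigenvalue, and adds components greedily until
  the cumulative share of the grand total reaches the threshold (default
  90%, the comparison being ≥), with a floor of one component per level.
  A per-level threshold variant is not provided; the pooled rule is the
  package's reading of a "total variation explained" criterion.
* **Scores.**  Joint best linear unbiased prediction per subject: stack the
  observed residuals of all the subject's days and solve the mixed-model
  normal equations (ZᵀZ + σ²Λ⁻¹ + 1e−8·I)θ = Zᵀr, where θ holds the shared
  subject scores and the per-day scores.  With full observation and σ² = 0
  this is exactly least-squares projection; with σ² > 0 scores shrink toward
  zero; zero-variance components are pinned to score 0.  The subject score
  is a single value shared across that subject's days by construction.
* **Reconstruction.**  Nested stages μ; μ+η_j; +level-1 sum; +level-2 sum.
  Training residual sum of squares is non-increasing across stages.
* **Variance accounting.**  rho = Σλ⁽¹⁾ / (Σλ⁽¹⁾ + Σλ⁽²⁾) over the full
  truncated-nonnegative spectra, not just the retained components;
  per-component shares are within-level fractions of the same totals.

## POPAI comparator

Inactive sitting is VA < 75 cpm, strictly — a minute exactly at the
cut-point is active.  Rescaled final-fraction minutes are classified on
their rescaled cpm (cpm is computed first, classification second; each such
minute counts as one minute).  Daily averages divide by the participant's
number of valid wear days, so inactive + active equals average daily valid
sitting time exactly.

## Association layer

Per outcome (SBP, DBP), one OLS enters both PC scores jointly and one enters
both POPAI summaries jointly, each controlling for age, race (ref
non-white), college education (ref below), employment (ref not working),
BMI, hypertension (ref no), number of valid concurrent wear days and average
daily non-sitting minutes; binaries are 0/1, analysis is complete-case with
the dropped count logged.  Focal predictors are z-scored on the analysis
sample and the model refit; this linear reparameterization leaves p-values
unchanged (asserted at 1e−10).  The eight focal p-values form one
Benjamini–Hochberg family.  Minute-scale POPAI coefficients also get a
per-hour convenience column (beta × 60, reported unrounded: a 0.021 mmHg/min
estimate reads 1.26 mmHg/h).  Designs with condition number above 1e10 are
rejected naming the columns.

## Synthetic data: what it emulates, and what it does not

* **Model-level curves** are exact draws from the two-level model: Gaussian
  scores with the specified eigenvalues, disjoint orthonormalized Fourier
  shapes as eigenfunctions (any orthonormal truth suffices for recovery
  tests; estimated eigenfunctions from real cohorts are data outputs, not
  inputs), iid Gaussian noise.  `reference_curve_truth` fixes the study-like
  configuration used throughout: 2 subject-level + 6 day-level components,
  subject-level share rho = 0.284, spectrum chosen so the pooled 90% rule
  needs all eight components; `simple_curve_truth` gives well-separated
  spectra for recovery experiments.
* **Block missingness** is missing-completely-at-random given bout length —
  the weakest mechanism consistent with an estimator that accommodates data
  missing at random.  The probability that a length-b block is absent rises
  from 0.8% at b = 1 to 93% at b = 60 along a beta-CDF-shaped curve whose
  two shape parameters were solved so the mean unregistered rate across
  lengths is 71% and the length-weighted overall cell-missing rate is 83% —
  the four rates observed in a reference cohort of postmenopausal women.  (A
  plain logistic through the two endpoints cannot reproduce the other two
  rates: it gives 54% overall.)  `missingness_curve_for_overall` tilts any
  base curve on the logit scale to hit a target overall rate exactly.
* **Device streams** are generated at the 1-second count level (no 30 Hz
  accelerations, device calibration, or proprietary count algorithm).  Days
  alternate sitting with standing/stepping segments (exponential durations);
  per-second axis counts are Poisson with per-minute intensities —
  zero-inflated lognormal for sitting, calibrated so minute-level sitting VM
  has median ≈ 20 cpm and a long tail toward ≈ 1000 cpm at the 97.5th
  percentile (used as a plausibility check, not a fitted target).  Days open
  and close with ≥ 3 upright minutes so overnight zero-count runs end exactly
  at the waking-window bounds; this makes the generator's schedule an exact
  oracle for the preprocessing chain, and fixtures exploit that.  Scripted
  schedules (constant per-second counts) override the stochastic model for
  hand-checkable cases.
* **Outcomes** are linear in the subject-level scores plus covariates with
  Gaussian noise and a returned design matrix, so closed-form OLS is the
  oracle.  Covariates mimic an older, overweight, mostly white female cohort
  (age ≈ 68 ± 7, BMI ≈ 32 ± 5, ~52% hypertensive).

What passing tests therefore show: the estimator chain recovers the
generating mean, eigenstructure, variance split, scores and regression
coefficients under the stated missingness mechanism, and the preprocessing
chain is exact on schedules it can see the truth for.  What they do not
show: behavior under informative missingness (e.g. sicker participants
registering fewer long bouts), non-Gaussian count noise, posture
misclassification, or clock drift between devices — none of which the
generators emulate.

## The missingness pseudo-simulation

Per replicate: simulate complete curves, fit; mask with the bout-length
curve, refit; compare the leading subject-level eigenfunction (absolute
cosine after sign alignment) and subject scores (Pearson correlation after
the same alignment) between the two fits.  Comparison against the complete
fit is the default — it isolates the effect of missingness from estimator
error; comparison against the generating truth is available
(`compare="truth"`).  Metrics are invariant to either fit's sign convention.
Masked refits use `on_empty_columns="drop"` (fit on the observed subgrid,
zero-pad results back) so extreme curves — e.g. only 1-minute bouts
surviving — produce a degraded report rather than an error.

## Problem sizes and numerical defaults

Simulation experiments run at B = 15 (T = 120), n = 300 subjects, 4 days
each — large enough for stable moment estimates, small enough that a full
fit takes well under a second; device-stream fixtures use 1–2 participants
for 1–3 days.  Numerical constants: orthonormality tolerances 1e−8 (truth)
and 1e−6 (fits); BLUP jitter 1e−8; eigenvalue floor 1e−12 relative;
condition-number limit 1e10; covariance-smoothing bandwidth 1.5 grid units.
Degenerate inputs are defined behavior: all-zero residuals give a zero
model; a single-column grid has no off-diagonal, so σ² is reported as 0
there; an all-missing row is rejected in scoring, and rows with no observed
cell are dropped at masking time.

## Known limitations

* η_j is indexed by within-subject day order; if day order carries meaning
  that differs across subjects (weekday/weekend mixes), the shift conflates
  them.  A 3-level (participant/visit/day) extension is out of scope.
* The non-wear detector is a simplified stand-in for the full count-based
  rule; on the synthetic streams they agree by construction of the fixtures.
* σ² estimation by diagonal extrapolation assumes the signal covariance is
  locally smooth along the diagonal; across bout-block boundaries this is
  only approximate.
* The pooled ≥-threshold selection rule with near-equal eigenvalue shares
  sits close to the decision boundary by nature; component *counts* are less
  stable than the eigenfunctions and variance shares themselves.
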