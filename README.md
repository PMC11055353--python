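# sitfpca

Multilevel functional principal component analysis (MFPCA) of accelerometer
activity counts within posture-derived sitting bouts.

## The problem

Sedentary behavior is usually measured with either a movement sensor (waist
accelerometer producing tri-axial activity counts) or a posture sensor
(thigh accelerometer classifying sitting/standing/stepping).  Combining
both streams lets one ask a sharper question: *how much does a person move
while they are sitting, and does that pattern relate to health?*  `sitfpca`
implements the full analysis chain for that question on time-matched device
data, and ships synthetic-data generators with known ground truth so every
stage is testable without access to a cohort:

1. **preprocess** — waking-wear windows from sleep logs, non-wear detection
   from zero-count runs, extraction of concurrent waking-wear sitting bouts,
   minute aggregation of 1-second counts (vector magnitude
   VM = √(VA² + HA² + PPA²), trailing fractions < 30 s dropped, otherwise
   rescaled by 60/f), and validity filters (5–15 h sitting per day, bouts
   ≤ 60 min, ≥ 1 valid day per participant).
2. **registration** — bouts ordered by length b = 1..B are concatenated onto
   a common grid of T(B) = B(B+1)/2 minutes (1830 for B = 60); minute m of a
   b-minute bout always sits at t = b(b−1)/2 + m.  Same-length bouts in a day
   are averaged; absent lengths leave their whole block missing.
3. **mfpca** — the two-level model

   X_ij(t) = μ(t) + η_j(t) + Σ_k ξ_ik φ_k⁽¹⁾(t) + Σ_l ζ_ijl φ_l⁽²⁾(t) + ε_ij(t),

   with subject-level (between) and day-level (within) eigenfunctions,
   ξ_ik ~ N(0, λ_k⁽¹⁾), ζ_ijl ~ N(0, λ_l⁽²⁾), ε ~ N(0, σ²).  Method-of-moments
   covariance surfaces, eigenanalysis, pooled 90%-of-variance component
   selection, joint per-subject BLUP scores under missingness, and
   incremental reconstruction (μ → +η → +level-1 → +level-2).
4. **popai** — the cut-point comparator: each sitting minute is inactive if
   VA < 75 cpm, active otherwise; daily averages per participant.
5. **association** — OLS regressions of systolic/diastolic blood pressure on
   the two subject-level PC scores (or the two POPAI summaries) controlling
   for baseline covariates, with standardized refits and Benjamini–Hochberg
   FDR across the 8 comparisons.
6. **missingness** — a pseudo-simulation quantifying how block missingness
   (unregistered bout lengths) degrades recovery of the leading
   subject-level component.
7. **synthetic** — generators for model-level curves (with truth scores),
   cohort-calibrated block missingness, 1-second device streams with a
   scripted or stochastic sit/stand/step schedule, baseline covariates and
   outcomes with known coefficients.

## Worked example

```bash
python examples/simulate_and_fit.py
```

draws 300 subjects × 4 days on the B = 15 domain (T = 120) from a truth with
2 subject-level and 6 day-level components and fits the model:

```
retained components: N1=2 (subject level), N2=6 (day level)
subject-level variance share rho: 0.280 (truth 0.284)
noise variance sigma^2: 0.251 (truth 0.250)
...
subject-level eigenfunction |cosine| vs truth: [0.957 0.958]
```

The pooled 90% rule recovers the generating component counts, the
between-subject share of variance (rho) and the noise variance; the cosine
similarities say the estimated subject-level eigenfunctions point along the
generating patterns.  The other examples exercise the remaining stages:

* `examples/device_pipeline.py` — 1-second streams → bouts → registered
  matrix → POPAI summaries and missingness bookkeeping;
* `examples/association_demo.py` — the 8-comparison blood-pressure table,
  recovering a generating coefficient of 2.0 mmHg per SD of PC1 on DBP
  (prints beta = 1.869, se 0.573, adjusted p = 0.0100);
* `examples/missingness_study.py` — with ~82% of cells masked in whole bout
  blocks, the subject-level PC1 of the masked fit still matches the
  complete-data fit (mean |cosine| 0.904, mean score correlation 0.863).

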