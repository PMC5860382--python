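# Methods notes

## What the package models

A validation study of spot-urine sodium equations has three layers, and the
package mirrors them:

1. **Collection processing.** Per-void records (timestamp, volume, Na/K/
   creatinine concentrations) are reduced to (a) up to four timed spot
   specimens per day and (b) one quality-controlled 24-hour excretion total
   per day. Analyte totals are volume-weighted sums of void concentrations,
   rescaled by 24/duration to a 24-hour basis.
2. **Prediction.** Each spot specimen is pushed through the four published
   equations, giving an equation x window grid of predicted 24-h sodium.
3. **Agreement.** Predictions are compared with the same day's measured
   total: group mean bias with CI, Bland-Altman relative bias with 95%
   limits of agreement, Spearman rank correlation and ICC, all stratified by
   sex x race and optionally hypertension/diuretic/eGFR strata; duplicate
   collection days feed a within/between-person variance decomposition.

## Collection rules and their literal edges

* Timed windows are minute-resolution and inclusive at both ends:
  overnight 04:00-12:00 (requires the self-reported first-void-after-longest-
  sleep flag), morning 08:30-12:30, afternoon 12:31-17:30, evening
  17:31-23:59. The overnight and morning windows overlap, so a single void
  may legitimately serve both; the code allows this and logs it.
* Completeness thresholds follow the study wording literally: total volume
  **>= 500 mL** (inclusive), duration **> 20 h** (strict — exactly 20 h
  fails), no menstruation during collection, at most one missed or spilled
  void. Every failed criterion is recorded as a reason; the verdict is
  complete iff the reason list is empty.
* Hypertension: BP **> 140/90** (strict, per the study text) or on
  BP-lowering medication, with a `strict_gt=False` switch for the
  conventional >=140/>=90. The four-level classification needs both BP
  readings; missing BP raises rather than guessing control status.
* The sensitivity filter keeps collections with measured-to-expected 24-h
  creatinine **>= 0.6** (inclusive), expected creatinine from the Mage-form
  anthropometric equation.
* Overnight identification is *not* inferred from inter-void gaps in observed
  data — the flag must be present. (The synthetic generator sets the flag
  from its own simulated sleep gap, which it knows by construction.)

## Equations, units, coefficients

Spot concentrations enter as Na/K in mmol/L and creatinine in mg/dL. Each
equation declares a unit dialect; conversions are explicit and logged
(mg/dL -> mg/L is x10; -> mmol/L divides by 11.312, molar mass 113.12 g/mol;
-> g/L divides by 100). Outputs are mmol/day converted at 23.0 mg/mmol
(configurable).

Coefficients are data, not code: `data/coefficients.yaml` carries
`{equation -> strata -> terms}` plus form, windows, dialect and exponent.
The INTERSALT set is the with-potassium variant (sex-specific; women include
an age^2 term). Tanaka and Kawasaki use their published linear expected-
creatinine equations (Kawasaki sex-specific). The Mage expected-creatinine
uses the power form CER (mg/day) = k (140 - age) W^1.5 H^0.5 / 1000 with
sex x race constants representative of the published Mage-form values; these
constants are the least standardized numbers in the literature and are
deliberately the easiest thing to swap via a config override.

Predictions that come out <= 0 are flagged `nonphysical`, never clamped —
clamping would silently bias group means. Missing potassium fails INTERSALT
for that specimen rather than imputing zero. Kawasaki defaults to morning
specimens only (`window_policy="relaxed"` lifts this), because its source
specimen was a second morning void and applying it elsewhere changes its
bias substantially.

## Statistical conventions

* The bias CI multiplier is exactly 1.96 (normal) while the p-value uses the
  paired t distribution. At the study's cell sizes (n ~ 100-550) the
  difference is cosmetic, but both conventions are kept as stated rather
  than harmonized.
* Sample SDs use the n-1 denominator throughout, including limits of
  agreement.
* ICC is one-way random effects, single measure (ICC(1,1)); the variant name
  travels in the output metadata since the choice is conventional.
* Variance components use the balanced two-replicate method of moments
  (ANOVA-equivalent): within = mean(d_i^2/2), between = var(person means)
  - within/2, floored at zero with a warning (ratio then reported missing).
  The estimator is exactly invariant to day relabelling.
* Subgroup CIs use stratum-specific SDs, not pooled ones.
* Significance is nominal at 0.05 with no multiplicity correction, matching
  the validation-study convention for cell-wise bias tables.
* Grid cells with fewer than 3 pairs are marked `insufficient_n`;
  Kawasaki x non-morning cells are `not_applicable`, giving 13 populated
  cells per stratum under defaults.

## The synthetic cohort

The generator targets the *statistical structure* of the motivating study,
not renal physiology:

* Demographics: n = 554; 56% female, 57.6% African American, 51%
  hypertensive, 15.9% diuretic users; age ~ N(60.3, 9.1) truncated to
  [45, 79]; BMI ~ N(30.0, 6.5); sex-specific heights, weight solved from
  BMI. Blood pressures are drawn consistently with each participant's
  hypertension/treatment/control flags.
* Usual sodium: lognormal person and day effects. For a stratum with
  configured raw mean m and SD s (white men 3,926/1,623; white women
  2,480/1,079; African-American men 3,454/1,651; African-American women
  3,397/1,641 mg/day), the total log-variance ln(1+(s/m)^2) is split by the
  race's configured within:between ratio (1.5 African American, 1.1 white)
  **on the log scale**: ratio r gives within = r/(1+r) of the total. Raw
  mean and SD are matched exactly by lognormal moment matching.
* A random third of participants get a second collection day (new day
  effect, same person effect).
* Voids: count ~ Poisson(9) redrawn into [3, 23]; times avoid a simulated
  sleep gap (~23:15 to ~06:45), and the void after the longest gap carries
  the first-after-sleep flag. Daily totals are partitioned over voids by
  Dirichlet weights; sodium, potassium and creatinine shares follow an
  evening-heavy diurnal profile (weights 0.7/0.9/1.0/1.3 for night/
  overnight-morning/afternoon/evening), volumes an exchangeable Dirichlet —
  so evening spot concentrations run highest for both analytes while the
  Na/Cr ratio stays comparatively stable, as urine dilution affects both
  analytes through the shared volume. Partitioning conserves day totals
  exactly.
* Daily creatinine is the participant's Mage-form expected creatinine times
  mean-corrected lognormal day noise (sigma 0.20), so the ratio-based
  equations and the creatinine completeness filter see a realistic joint
  structure. Potassium gets its own person/day lognormal split (mean 60,
  SD 20 mmol/day). Daily volume is lognormal around 1,838 mL; duration
  N(24, 0.5) h clipped to [21, 26]; 2% report a missed void, 1% of women
  menstruation — under defaults ~99% of collections pass completeness.
* `noise_scale=0` collapses every random spread: both days equal the latent
  usual sodium exactly, which anchors the conservation tests.

**Two calibration facts worth knowing.** First, a ratio configured on the
log scale is recovered slightly larger by the raw-scale moment estimator
(lognormal distortion): at the African-American noise level the raw-scale
within:between ratio is ~1.66, at the white level ~1.20. Second, the
configured ratios are per-stratum parameters; estimating them on a pooled
race group adds the between-sex mean gap to the between-person variance.
For African Americans the sexes have nearly equal means so pooling is
harmless, but for whites the 3,926 vs 2,480 mg/day gap pushes the pooled
ratio down to ~0.74. Recovery experiments therefore run within homogeneous
race x sex strata. A generator calibrated to the published stratum SDs
cannot simultaneously reproduce a pooled-race ratio and those SDs; the
per-stratum interpretation was chosen and is visible in the pooled numbers
the analysis scripts print.

**What the generator does not emulate** — and hence what green tests do not
show: real diet-driven intake correlation between days, assay error, the
equations' true error structure against physiology (the synthetic spot
specimens are *constructed* from the day totals, so equation biases on
synthetic data reflect the equations' functional forms applied to an
idealized excretion process, not their field validity), seasonal or
weekday effects, and any sodium-retention physiology. The pipeline's
individual-level correlations on synthetic data happening to fall in the
study's observed range is a realism check, not a reproduction.

## Benchmark experiment design

* Published-table bias arithmetic: paired samples are synthesized with
  re-centred Gaussian noise so group means hit the published summary values
  exactly; `mean_bias` then reproduces the difference of group means to
  float precision (mean-of-differences identity). The published moments are
  inputs here, not targets of simulation.
* Variance-ratio recovery runs 400 replicate cohorts at the study's
  duplicate-day subgroup sizes (111 African-American, 75 white pairs). The
  per-replicate ratio estimator is heavily right-skewed (noisy denominator),
  so the unbiased within/between component estimates are pooled across
  replicates before forming the ratio, the way ANOVA sums of squares pool
  across replicate studies.
* Generator calibration averages empirical stratum means/SDs over 6
  replicates of n = 5,000 draws: the SD of a lognormal with CV ~ 0.48 has
  ~1.8% relative sampling error at n = 5,000 on its own, so single-replicate
  moments would mostly measure sampling noise.
* CI coverage injects a fixed 250 mg/day offset into 500 replicate paired
  samples of n = 200 and counts how often the 1.96 x SEM interval covers it.
* Equation-oracle agreement evaluates 1,000 random valid inputs against
  one-line re-evaluations of each formula written independently of the
  configurable equation layer.

Problem sizes throughout (554-participant cohorts, 400 recovery replicates,
10,000-point agreement samples) were chosen so the whole suite runs in well
under a minute while keeping Monte-Carlo noise far from every tolerance.

## Known limitations

* Mage expected-creatinine constants are config defaults, not authoritative
  transcriptions; swap them for any preferred published set.
* The duplicate-day design supports only the balanced two-replicate
  decomposition; more days per person would need a general mixed model.
* The Bland-Altman layer reports limits of agreement but no regression-based
  proportional-bias test; the plots make the trend visible but it is not
  formally tested.
* Completeness relies on self-reported duration/menstruation/missed-void
  fields being present and truthful; there is no imputation path.
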