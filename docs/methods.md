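# Methods

## The screening analysis

The package implements a cross-sectional screening analysis for elevated
blood pressure built on derived anthropometric indices. One record per
adult subject (18–80 years) carries raw body measurements, a single
SBP/DBP/pulse reading and an antihypertensive-treatment flag. The analysis
proceeds in four stages:

1. **Indices.** Nineteen indices are computed per subject — BMI, WHR and
   WHtR as traditional comparators and sixteen emergent body-shape scores
   (AWI, HWrI, WWrI, WHHR, W/Ht², W/Ht³, H³/W³, wBMI, PI, BRI, BAI, ABSI,
   CI, BFDI, AVI, PMI).
2. **Classification.** Blood pressure is categorised per JNC7; each
   flagged index is dichotomised at a tertile boundary of the analysis
   cohort.
3. **Association.** Each binary risk flag is related to prehypertension
   (vs normotension, hypertensives excluded) and to hypertension (vs
   normotension, prehypertensives excluded) with logistic models. The
   pooled model adjusts for age and sex; sex and sex×age strata adjust
   for age.
4. **Discrimination.** A covariate-adjusted AUC is computed per index ×
   outcome × stratum and tables are ranked by AUC.

The outcome contrasts use normotensives as the common reference because
each outcome is reported as its own odds ratio; with three ordered
categories this "each case group vs the reference" design is the standard
reading and keeps the two contrasts independent of each other's case mix.

## Unit conventions for the index formulas

Published formula collections for these indices mix centimetres and
metres freely, and several printed unit annotations are mutually
inconsistent with the magnitudes the same sources report. This package
fixes one convention per index, chosen so each formula reproduces the
reference population's central values:

- waist enters in **metres** in WHtR, H³/W³, wBMI, BRI, ABSI and CI; in
  **centimetres** in AWI, WWrI, W/Ht², W/Ht³, BFDI and AVI;
- height is always in metres; weight in kg;
- PI = weight/height³ with height in metres (median ≈ 17.5; a cm height
  would shift it by 10⁶);
- PMI divides by **1730**, not 1.730 — the thousands-separator reading is
  the only one that puts the median near 1.1 at pulse ≈ 70 and BMI ≈ 27;
- BFDI is read as ((WC/height) + (1/height)) / WHR (magnitude ≈ 65), the
  only bracket placement consistent with its reported scale;
- AVI's inner term is read as (WC − hip)², the standard abdominal-volume
  definition (litre-scale result).

One known irreducible inconsistency: ABSI computed as printed,
WC_m/(BMI^{2/3}·√h), has magnitude ≈ 0.081 for a median adult, whereas
reference tables for this population print ≈ 0.100. The computation that
produced the published ABSI values cannot be recovered from the published
formula, so the formula is implemented exactly as printed. Because risk
cutoffs are always re-derived from the analysis cohort's own tertiles,
every downstream result (flags, odds ratios, AUC) is invariant to any
monotone rescaling of an index, and this discrepancy does not propagate.
The units-regression test therefore covers the other 18 indices.

## Classification rules

- **JNC7**: SBP bands <120 / 120–139 / ≥140 and DBP bands <80 / 80–89 /
  ≥90 are combined by the *more severe* of the two, which is JNC7's own
  rule; treated subjects are hypertensive regardless of the reading.
  Categories are exhaustively tested for partition and monotonicity over
  the integer grid SBP 80–200 × DBP 40–120.
- **Tertile cutoffs**: "risk above the second tertile" is implemented as
  value ≥ the 33.33rd percentile (so the upper two-thirds are flagged),
  and "above the third tertile" as ≥ the 66.67th percentile (upper third
  flagged). The first reading is forced by the observation that published
  BRI cutoffs for this design lie *below* the population median. Tertile
  flags are boundary-inclusive (≥); the PMI rule is strict (> 1), as
  published. H³/W³ decreases with adiposity and has no published cutoff
  rule, so it is computed, described and correlated but never flagged:
  association and ROC tables carry 15 emergent rows.
- **Cutoff provenance**: cutoffs are derived once on the full analysis
  cohort and reused across strata (screening thresholds are meant to be
  population-wide, and per-stratum tertiles would change the flag's
  meaning between table rows). The cutoff set records a fingerprint
  (n + value hash) of its derivation cohort.
- When `include_traditional` is on, waist circumference, BMI, WHtR, WHR
  and visceral fat are added to the ROC tables as comparators, dichotomised
  by the upper-tertile rule — the natural analogue for markers that rise
  with adiposity (no published rule exists for them in this design).

## Statistical kernel

- **Rank/contingency tests** (Spearman with midrank ties and t-approximate
  p; Mann–Whitney U, exact when min(n) ≤ 8 and tie-free, otherwise normal
  approximation with tie correction and no continuity correction; Pearson
  chi-squared without Yates correction; pooled-variance t) are thin,
  convention-pinning wrappers over scipy.stats.
- **Logistic regression** is Newton–Raphson/IRLS written in-module:
  convergence when max |score| < 1e-8 or the relative log-likelihood
  change < 1e-10, at most 50 iterations; covariance is the inverse
  observed information at the optimum. A coefficient escaping beyond ±15
  on the logit scale is declared (quasi-)complete separation and the fit
  is returned flagged non-converged — downstream cells become explicit
  NAs with a reason code instead of absurd numbers. The fit is
  cross-checked against statsmodels in the test suite, and against the
  Woolf closed form on 2×2-reducible designs.
- **Odds ratios** are Wald: OR = exp(β), CI = exp(β ± 1.96·SE), two-sided
  normal p. No multiple-testing correction is applied anywhere (p < 0.05
  is reported as-is); with ~15 indices × 2 outcomes × 7 strata this is a
  deliberate mirror of screening practice, and the suite instead verifies
  that the *null* false-positive rate of the whole machinery is nominal.
- **AUC** is the Mann–Whitney estimator, (concordant + ½·ties)/(n₁n₂),
  computed from midranks; it is invariant under monotone transforms and
  satisfies AUC(a,b) + AUC(b,a) = 1 exactly.
- **Covariate-adjusted AUC**: "adjusted by age" is implemented
  model-based — fit outcome ~ intercept + flag + age (+ sex in the pooled
  stratum), score subjects by fitted probability, take the AUC of those
  scores. Published screening reports rarely state their adjustment
  mechanism; plausible alternatives (covariate-specific ROC, placement
  values, stratified AUC pooling) exist, and the model-based choice was
  made because it extends naturally to multiple covariates and to the
  bootstrap. The unadjusted AUC of the raw flag is recoverable via
  `anthro.stats.auc` directly. The 95% CI is a percentile bootstrap over
  subjects (default 1000 replicates; ≥ 200 recommended for a stable CI;
  `bootstrap_reps=0` skips the CI entirely for point-estimate-only runs).
  Bootstrap replicates that lose an outcome class or separate are skipped;
  if fewer than half survive, the CI is reported NA.

Every stochastic cell draws its seed from the run seed combined with a
CRC of its (stratum, outcome, index) labels, so any one cell's stream is
stable no matter which other cells run.

## Synthetic cohort generator

The generator stands in for the unreleased field data and defines the
package's study conditions:

- **Sex split** 852:298 female:male per 1150 (prop_female ≈ 0.741).
- **Marginals**: age is truncated log-normal on [18, 80]; every body
  measure and pulse is log-normal, parameterised by (median, p95) — the
  right-skewed family is consistent with the asymmetric 5th–95th bands
  reported for such populations, and (median, p95) pins (μ, σ) in closed
  form. Per-sex medians follow the reference population's Table of
  descriptives; hip, wrist and arm medians (not printed there directly)
  are back-solved from the printed ratio indices (WHR, HWrI, AWI), and
  pulse from PMI and BMI.
- **Dependence**: a Gaussian copula over (height, weight, waist, hip,
  wrist, arm, body fat, visceral fat, pulse). The headline correlations
  are waist–weight 0.85, waist–hip 0.80, weight–height 0.45,
  weight–wrist/arm 0.60, background 0.20; weight–hip had to be raised to
  0.65 and the waist/hip–wrist/arm block set to 0.45–0.50 because the
  naive background value makes the matrix indefinite next to the two 0.8+
  entries. The matrix is validated positive-definite at construction.
- **Blood pressure**: SBP = 90.15 + 0.45·age + 7.0·z_waist + 7.9·I(male)
  + ε_s, DBP = 63.04 + 0.22·age + 4.0·z_waist + 1.44·I(male) + ε_d, with
  (ε_s, ε_d) bivariate normal, SDs 14.5/9.0 mmHg, correlation 0.6, and
  z_waist the latent copula score for waist (so the adiposity effect is
  expressed per SD of waist). Draws violating DBP < SBP or the physiologic
  ranges are re-drawn. These constants were calibrated once by simulation
  and then frozen: at n = 10⁵ the implied per-sex medians sit within 3% of
  their targets and the category mix is ≈ 29.9% prehypertension / 14.2%
  hypertension (targets 29.74/14.35).
- **Treatment**: P(treated) = logistic(−6 + 0.07·age), a small,
  age-skewed subgroup (≈ 6%) classified hypertensive by fiat.
  Smoking/alcohol/sedentary flags are independent Bernoulli at the
  published per-sex frequencies.
- **Effect presets**: `null_adiposity_params()` zeroes the adiposity
  coefficients (no index can beat AUC 0.5); `planted_bri_or2_params()`
  scales them by 0.65, the value calibrated so the pooled age+sex-adjusted
  BRI-flag odds ratio for prehypertension is 2.0 — the package's
  parameter-recovery ground truth.
- One seed feeds per-stage child streams (ages, per-sex body blocks, BP
  noise, treatment/lifestyle), so adding a column to one stage never
  perturbs another; generation is bit-reproducible for fixed
  (params, seed). Measured values are rounded to realistic instrument
  precision (heights mm, circumferences/weights 0.1, pressures/pulse
  integer), and DBP is lowered by 1 mmHg in the rare case integer
  rounding collides the pair.

**What the generator does not emulate**: measurement error structure,
digit preference in manual sphygmomanometry, age–adiposity correlation
(body measures are independent of age by construction, which is exactly
what makes the null-generator type-I experiment clean), household or site
clustering, and any joint structure beyond the single Gaussian copula.
Tests passing on this generator therefore demonstrate the *machinery* —
formulas, thresholds, models, ranking — not epidemiological claims about
any real population.

## Numerical choices

- Percentiles everywhere (descriptives and tertiles) use linear
  interpolation between closest ranks, h = (n−1)p + 1 (NumPy's default);
  one documented convention beats silent divergence between stages.
- H³/W³ is summarised as mean ± SD (its customary reporting) and compared
  between sexes by pooled t; every other descriptive row uses median
  (p5–p95) and Mann–Whitney.
- Degenerate descriptive cells (constant in both groups, < 2 members)
  yield NaN p-values, not errors; degenerate model cells (single outcome
  class, separation, singular information) yield rows flagged
  `defined=False` with a reason code, and the run continues.
- Boundary age equal to the cut (default 40) goes to the younger stratum.

## Problem sizes

The test suite exercises the dual-implementation index oracle at 1000
records, tertile oracles at 200 random vectors, Wald coverage at 500
replicates of n = 1000, the null type-I experiment at 200 cohorts of
n = 800, planted-effect recovery at n = 5000, and generator calibration at
n = 10⁵ — sizes at which the Monte-Carlo bands in the assertions are
comfortably wider than simulation noise. The acceptance script uses the
same sizes and completes in well under a minute.

## Known limitations

- Wald intervals are first-order; very sparse strata (a handful of cases)
  are reported as unstable or undefined rather than bridged with exact or
  penalised (Firth) methods, which are out of scope.
- The bootstrap CI for the adjusted AUC is percentile-method only; no
  DeLong-type covariance between correlated AUCs is computed, so the
  tables rank point estimates without joint inference.
- A single BP reading per subject is assumed; averaging repeated readings
  is left to the data producer.
- The ACC/AHA 2017 blood-pressure categories are deliberately not
  implemented; the JNC7 scheme is the fixed contract of this analysis.
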