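# anthro

Anthropometric body-shape indices as screening markers for prehypertension
and hypertension.

`anthro` is a small biostatistics toolkit for the common epidemiological
design in which cheap, non-invasive body measurements (waist, hip, wrist
and arm circumferences, height, weight, body fat, pulse) are turned into
derived body-shape indices and evaluated as risk markers for elevated
blood pressure. It is aimed at analysts who have — or want to simulate — a
cross-sectional adult cohort with one blood-pressure reading per subject.

It provides, end to end:

- **An index engine** computing 3 traditional indices — BMI = w/h²,
  waist-to-hip ratio WHR, waist-to-height ratio WHtR — and 16 emergent
  ones, including the body roundness index
  BRI = 364.2 − 365.5·√(1 − ((WC/2π)/(0.5·h))²),
  a body shape index ABSI = WC/(BMI^{2/3}·h^{1/2}),
  the conicity index CI = WC/(0.109·√(w/h)),
  the abdominal volume index AVI = (2·WC² + 0.7·(WC − hip)²)/1000,
  and the pulse mass index PMI = pulse·BMI/1730 (WC in metres where the
  published magnitudes require it; see `docs/methods.md` for the full
  unit conventions).
- **JNC7 blood-pressure classification** (normal < 120/80, prehypertension
  120–139 or 80–89, hypertension ≥ 140 or ≥ 90 mmHg, the more severe band
  winning; antihypertensive treatment forces the hypertensive class) and
  WHO BMI classes.
- **Data-driven risk cutoffs**: each index is dichotomised at a tertile
  boundary of the analysis cohort itself (upper two-thirds for BRI, wBMI
  and PI; upper third for the rest; PMI at the fixed threshold > 1).
- **A statistical kernel**: logistic regression by iteratively reweighted
  least squares with Wald odds ratios and explicit separation handling,
  the Mann–Whitney AUC estimator, and a covariate-adjusted AUC (model-based
  scores from outcome ~ flag + age (+ sex), bootstrap percentile CI).
- **A study pipeline** producing the full stratified report — descriptives,
  Spearman correlations with SBP/DBP, odds ratios and AUC rankings for
  preHTN and HTN versus normotension, in total / by sex / by sex × age
  (≤40 vs >40 years) strata.
- **A calibrated synthetic-cohort generator** (Gaussian copula over
  log-normal marginals plus a linear blood-pressure model) whose defaults
  reproduce the reference screening population: 852 women and 298 men per
  1150 subjects, the published per-sex medians, and ≈30% prehypertension /
  ≈14% hypertension.

## Worked example

```python
from anthro import default_params, generate_cohort, run_study, StudyConfig

cohort = generate_cohort(default_params(), seed=42)          # n = 1150
report = run_study(cohort, StudyConfig(bootstrap_reps=200, seed=0))

print(report.categories.round(2).to_string(index=False))
a = report.associations
row = a[(a.index_id == "BRI") & (a.outcome == "preHTN")
        & (a.stratum == "total")].iloc[0]
print(f"BRI flag, preHTN (age+sex adjusted): OR={row.odds_ratio:.2f} "
      f"95% CI ({row.ci_low:.2f}, {row.ci_high:.2f}) p={row.p_value:.2g}")
```

prints

```
       category  total_n  total_pct  men_n  men_pct  women_n  women_pct
   normotensive      651      56.61    144    48.32      507      59.51
prehypertension      313      27.22     96    32.21      217      25.47
   hypertension      186      16.17     58    19.46      128      15.02
BRI flag, preHTN (age+sex adjusted): OR=2.68 95% CI (1.94, 3.72) p=3e-09
```

i.e. in this simulated cohort 27.2% are prehypertensive and 16.2%
hypertensive, and subjects whose BRI lies in the upper two tertiles
(cutoff 4.50 in this cohort) have 2.7-fold higher odds of prehypertension
than normotension after age and sex adjustment. `report.auc` ranks every
index by covariate-adjusted AUC within each stratum × outcome, e.g. the
top pooled discriminators of hypertension here are AVI (AUC 0.773), CI
(0.768) and WWrI (0.767).

The same steps are available from the shell:

```bash
anthro simulate --n 1150 --seed 42 --out cohort.csv
anthro compute  --in cohort.csv --out panels.csv
anthro classify --in cohort.csv --out classified.csv
anthro study    --in cohort.csv --outdir results/
```

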