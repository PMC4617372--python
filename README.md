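# akidetect

Automated detection of acute kidney injury (AKI) from longitudinal serum
creatinine, for biostatisticians and informaticians who need to apply,
extend or validate laboratory e-alerting algorithms on routine biochemistry
extracts — without access to identifiable patient data.

AKI is diagnosed from a rapid creatinine rise relative to the patient's own
history. The deployed national e-alerting algorithm compares each index
creatinine `SCr(t)` with rolling references and alerts when any of three
criteria holds:

1. `SCr(t) / median{SCr(s): t−365 ≤ s ≤ t−8} ≥ 1.5`
2. `SCr(t) / min{SCr(s): t−7 ≤ s ≤ t−1} ≥ 1.5`
3. `SCr(t) − min{SCr(s): t−2 ≤ s ≤ t−1} > 26 μmol/L` (the 48-h criterion at day resolution)

Research extensions add a retrospective criterion (ratio ≥ 1.5 over the
minimum within 30 days *after* the index), a 3-year most-recent look-back,
and an 8–365-day minimum, giving strictly nested models A ⊆ B ⊆ C ⊆ D that
trade alert burden against sensitivity. Alerts are staged by the KDIGO
creatinine bands (Stage 1: rise > 26 or ratio ∈ [1.5, 2); Stage 2: ratio ∈
[2, 3); Stage 3: ratio ≥ 3, or ratio ≥ 1.5 with index > 354 μmol/L), using
whichever available reference yields the highest stage.

The package provides:

- `timeline` — the longitudinal data model: per-day deduplication (highest
  value per day, with a keep-all variant), chronic-RRT exclusion, window
  extraction, four-variable MDRD eGFR;
- `detector` — criteria 1–6, models A–D, staging, abnormal-no-baseline
  flags, patient-level first episodes with 30-day peak stage;
- `evaluation` — sensitivity against coded (ICD-10) AKI with exact binomial
  CIs, stage-stratified descriptor tables, alert burden, population
  incidence, small-cell suppression;
- `synthetic` — a seeded generator of realistic cohorts (testing-intensity
  strata, injected episodes with configurable magnitude/recovery,
  stage-dependent coding) with full ground truth;
- `io`/`cli` — CSV schemas, YAML configuration and the
  `akidetect simulate | detect | evaluate | run` commands.

See `docs/methods.md` for the model, its assumptions and the design
decisions.

## Worked example

```python
from akidetect import (SimulationConfig, simulate_cohort, dedup_daily_max,
                       DetectorConfig, detect_cohort, detection_vs_truth,
                       sensitivity_ci, incidence_pmp)

config = SimulationConfig(seed=1, n_patients=500)
tests, patients, truth = simulate_cohort(config)
tests = dedup_daily_max(tests)

dc = DetectorConfig(study_window=config.study_window)
episodes, alerts, flags = detect_cohort(tests, patients, "A", dc)
print(f"model A: {len(episodes)} alerted patients, "
      f"{len(alerts)} alerts, {len(flags)} no-baseline flags")

metrics = detection_vs_truth(episodes, truth)
print(f"sensitivity vs simulated truth: {metrics['sensitivity']:.3f} "
      f"({metrics['n_detected_true']}/{metrics['n_true_aki']} injected episodes)")

r = sensitivity_ci(300, 329)
print(f"published-count check: {r.sensitivity}% ({r.ci_low}-{r.ci_high})")
print(f"incidence: {incidence_pmp(5565, 438332).rate_pmp} per million per year")
```

prints

```
model A: 47 alerted patients, 106 alerts, 19 no-baseline flags
sensitivity vs simulated truth: 0.870 (47/54 injected episodes)
published-count check: 91.2% (87.6-94.0)
incidence: 12696 per million per year
```

The deployed model misses 7 of 54 injected episodes here — these are the
simulated patients who present with established AKI and no baseline test,
detectable only in retrospect (model B recovers them once their creatinine
falls). `sensitivity_ci(300, 329)` reproduces a published validation
headline from its counts: 300 of 329 coded-AKI patients detected, 91.2%
sensitivity with an exact 95% interval of 87.6–94.0.

## Analysis scripts

The numbered drivers under `analysis/` run the full study on a synthetic
working cohort and write their tables to `results/`:

- `01_simulate_cohort.py` — materialise the cohort, summarise its structure;
- `02_detect_alerts.py` — alert burden per criterion and per model;
- `03_evaluate_sensitivity.py` — sensitivity vs coded AKI, stage-stratified
  table (small cells suppressed), accuracy against ground truth;
- `04_headline_statistics.py` — published headline statistics recomputed
  from their validation counts.

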