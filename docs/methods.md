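# Methods

## The detection problem

Acute kidney injury (AKI) is recognised biochemically as a rapid rise in
serum creatinine relative to the patient's own recent history. An automated
e-alerting system embedded in a laboratory information system sees only the
stream of creatinine results; for each new (index) result it must decide,
from the patient's prior results alone, whether enough change has occurred
in a short enough time to warrant an alert. The difficulty is entirely in
the choice of the *reference* value: patients are tested irregularly, many
have chronic kidney disease (a stably raised creatinine that must not
alert), and a substantial minority present acutely with no recent test at
all.

`akidetect` implements the deployed national algorithm and the research
extensions around it, plus the validation analysis used to characterise
them, over plain tabular extracts.

## Criteria and models

Each index test is compared with up to six references derived from the
patient's own series:

| criterion | window                | reference              | trigger          |
|-----------|-----------------------|------------------------|------------------|
| 1         | 8–365 days ago        | median of window       | ratio ≥ 1.5      |
| 2         | 1–7 days ago          | lowest in window       | ratio ≥ 1.5      |
| 3         | 48 h (1–2 days ago)   | lowest in window       | rise > 26 μmol/L |
| 4         | 1–30 days *after*     | lowest in window       | ratio ≥ 1.5      |
| 5         | 1–1095 days ago       | most recent in window  | ratio ≥ 1.5      |
| 6         | 8–365 days ago        | lowest in window       | ratio ≥ 1.5      |

Criteria 1–3 constitute the deployed algorithm (**model A**). Criteria 4–6
are added incrementally to form models **B** (A + retrospective
future-minimum), **C** (B + 3-year look-back) and **D** (C + 8–365-day
minimum). The models are strictly nested, so the alerted-patient sets must
satisfy A ⊆ B ⊆ C ⊆ D on any input — this is asserted as a property test.
Criterion 6 dominates criterion 1 (a window minimum never exceeds its
median), which is likewise asserted.

Ratio thresholds are boundary-inclusive (a ratio of exactly 1.5 alerts);
the absolute-rise threshold is strict (a rise of exactly 26 μmol/L does
not). These follow the printed inequality directions of the algorithm
specification and are fixed defaults.

### Staging

Alert severity follows the KDIGO creatinine bands: Stage 1 for a rise
> 26 μmol/L or ratio in [1.5, 2); Stage 2 for ratio in [2, 3); Stage 3 for
ratio ≥ 3, or ratio ≥ 1.5 with an index above 354 μmol/L (three times the
upper reference interval when age < 18). When several references are
available the one yielding the highest stage is used; the absolute-rise
path to Stage 1 applies only to the 48-h reference. Episodes record both
the stage at first detection and the peak stage among alerts within 30
days, so progression to Stage 3 from a lower initial stage can be counted.

When only the retrospective criterion 4 fires (models B–D), the alert is
staged against the future-minimum reference. Without this extension,
retrospectively detected patients would be unstageable; it is documented
here as a package design choice.

### Day resolution

All comparisons run at whole-day resolution: routine extracts often lack
reliable sample times, so "48 h" is interpreted as the previous 1–2
calendar days. A configuration switch (`criterion3_window_days ∈ {1, 2}`,
default 2) narrows this to 1 day, reproducing the stricter sensitivity
variant. Window bounds are inclusive at both ends: "8–365 days ago" is
[t−365, t−8], "previous 7 days" is [t−7, t−1], "within 30 days after" is
[t+1, t+30]. Whether the original windows were closed at both ends is not
documented anywhere authoritative; this convention is fixed here and
exercised against a brute-force full-scan oracle in the tests.

Repeat same-day samples are collapsed to the highest value per (patient,
day) before detection — this prevents a spurious low sample from
manufacturing a rise — with a `keep_all` mode available as the
sensitivity-analysis variant in which every sample is evaluated.

### The no-baseline flag

An index value above the sex-specific adult upper reference interval
(defaults 110 μmol/L female, 120 male, configurable — reference intervals
are laboratory-specific and no single national value exists) with **no
prior test within the 3-year look-back** is flagged "abnormal, chronicity
uncertain" rather than alerted. Note this is deliberately wider than the
deployed system's 1-year rule: within this package the flag complements
the extended models, so it fires only when *no* look-back criterion (1, 5
or 6) could possibly have had a reference. A patient whose only prior test
is, say, 400 days old is not flagged here, whereas the deployed 1-year rule
would flag them.

### Exclusions

Patients receiving chronic renal replacement therapy are removed, with all
their tests, before detection — dialysis-dependent creatinine dynamics
would otherwise be misread as acute injury. The cohort is adult (≥ 15
years). Patients whose tests all fall outside the study window produce
nothing; incidence is per study year.

## Evaluation

Coded hospital-discharge diagnoses of acute renal failure are a highly
specific but insensitive subset of AKI. They therefore support only a
*sensitivity* analysis: the proportion of coded patients the biochemical
model alerted on, with a 95% binomial confidence interval —
Clopper–Pearson exact by default, Wilson as an option, with the method
recorded in the result. Specificity, predictive values and ROC analysis
against coded labels are deliberately not offered; they are available only
against synthetic ground truth (`detection_vs_truth`), where the complete
truth is known by construction.

Percentages are rounded half-up to one decimal; population incidence is
reported per million adult population per year, rounded half-up to the
nearest integer. Descriptor tables can pass through small-cell suppression
(counts below 5 rendered "<5", paired percentages masked, zeros exempt by
default) as used in disclosure-controlled publications.

## The synthetic cohort generator

No real extract can ship with the package, so `synthetic.simulate_cohort`
generates cohorts with the structural features the analysis depends on.
Per patient, driven by a substream spawned deterministically from the seed
(`default_rng([seed, patient_index])`, so output tables are byte-identical
across runs and platforms):

- **Strata.** A fraction `frac_abnormal_stratum` (default 0.6, matching the
  roughly 60/40 split of the motivating regional cohort) is drawn from an
  abnormal-kidney-function stratum: older (age ≈ N(74, 10) vs N(53, 16)),
  with higher comorbidity prevalences, and a baseline creatinine
  rejection-sampled from a sex-specific log-normal (medians 95/75 μmol/L,
  log-sd 0.25) conditioned on four-variable MDRD eGFR < 60 (≥ 60 for the
  normal stratum).
- **Testing process.** Background test days follow a per-patient
  homogeneous Poisson process with a gamma-heterogeneous rate (shape 1,
  scale 2 per year — median about two in-study tests per tested patient),
  over a span from one year before the study window to 30 days after it,
  so look-back and retrospective windows are both exercisable. Extra tests
  cluster within admission intervals (each inpatient day tested with
  probability 0.5), and injured patients receive a monitoring schedule on
  days {0, 1, 2, 3, 5, 7, 10, 14, 21, 30} after onset (each kept with
  probability 0.8; the peak day always).
- **Injected AKI.** With probability `aki_incidence` (default 0.10) an
  episode is injected: the peak fold-rise is drawn from a log-normal
  (log-mean 0.3, log-sd 0.4) truncated below at 1.5, ramps up linearly
  over 1–3 days and decays back with a 5-day half-life. The ramp peaks
  inside the study window, making every injected episode a study-year
  episode. A fraction `frac_no_baseline` (default 0.08) of injured
  patients present with established AKI: all their tests before the peak
  are removed. Otherwise a look-back baseline test is guaranteed.
- **Noise.** Multiplicative log-normal measurement noise with coefficient
  of variation `measurement_noise_cv` (default 0.05 — analytical plus
  short-term biological variation); values stored to 0.1 μmol/L.
- **Coding.** A coded-AKI label is drawn with probability depending on the
  true stage implied by the injected peak (defaults 0.025 / 0.082 / 0.279
  for Stages 1–3, the stage-stratified coded proportions observed in the
  motivating validation), and with a small false-coding probability
  (default 0.001) otherwise.

The generator emulates *structure*, not the cohort itself: magnitude,
recovery and testing-rate distributions are package choices (no
distributional detail is published), comorbidities are independent
Bernoulli flags rather than code-list derivations, and assay drift,
inter-laboratory variation and urine output are absent. Passing tests
therefore demonstrate that the algorithm implementation behaves correctly
on data with this structure — full recovery of injected episodes when
baselines exist and noise is off; recovery of no-baseline presentations
only through the retrospective criterion — not that the published cohort's
patient-level results are reproduced.

One consequence of faithful staging worth knowing: with multiplicative
noise, the "reference providing the highest stage" rule selects downward
noise excursions of the reference, so the detected peak stage drifts
upward relative to the injected stage in a few percent of episodes. In
stage-stratified tables this dilutes the higher-stage strata with
lower-stage patients and biases their coded fractions slightly downward —
visible when recovering the stage-dependent coding probabilities, which
succeed within binomial tolerance but sit systematically a little low at
Stage 3.

## Numerical and interface choices

- Dates are ISO 8601 externally and proleptic-ordinal integer days
  internally; all window arithmetic is integer.
- Window extraction is by binary search on the sorted per-patient day
  array; an even-count median is the mean of the middle two values.
- The MDRD equation is used in its four-variable form without an ethnicity
  coefficient (the emulated setting records none); every coefficient is
  overridable via `EgfrParams`.
- Unit handling is explicit: values are μmol/L throughout, with no
  automatic mg/dL conversion (the 88.4 divisor inside the eGFR equation is
  the only unit bridge).
- The CLI (`akidetect simulate|detect|run`) is a thin layer over the
  library; exit code 1 marks validation errors, 2 system errors. All
  randomness lives in the simulator; detection and evaluation are pure
  functions of their input files.

## Problem sizes

Tests and the acceptance script run on cohorts of 500–4000 patients
(seeded), the scale at which every property of interest — model nesting,
injected-episode recovery, stage-coding recovery at ~2000–3000 detected
episodes, interval coverage over 2000 binomial draws — is measurable with
comfortable statistical margins while the whole suite completes in a few
minutes on one CPU.

## Known limitations

- Day-level resolution cannot express true 48-hour windows or same-day
  deltas; whether a sub-day earlier sample may serve as a criterion-2/3
  reference is unanswerable at this resolution.
- Whether criterion-4-only detections were staged in the original
  validation is unknown; staging them against the future minimum is this
  package's documented extension.
- The generator's independence assumptions (comorbidities independent of
  AKI risk given stratum; constant true baseline outside episodes) are
  simplifications; parameter-recovery results should be read accordingly.
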