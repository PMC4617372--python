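"""Seeded synthetic longitudinal laboratory cohorts.

Real creatinine extracts with linked discharge coding cannot be shared, so
this module generates cohorts with the structure the detection and
evaluation stages assume: two kidney-function strata (abnormal eGFR < 60
and normal), heterogeneous per-patient testing rates (median around two
tests per patient-year), hospital admission intervals with clustered
inpatient testing, injected AKI episodes with a configurable fold-rise that
ramps up over a few days and decays exponentially, stage-dependent
probability of a coded discharge diagnosis, a small false-coding rate, and
a subset of injured patients with no baseline test in the prior year.

Everything is driven by one integer seed; per-patient substreams are spawned
deterministically, so the same (seed, config) pair reproduces the output
tables byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .timeline import CreatinineTest, day_number, mdrd_egfr

STUDY_2003 = (day_number("2003-01-01"), day_number("2003-12-31"))

# stratum-specific prevalences of the comorbidity flags (abnormal, normal)
_COMORBIDITY_PREV = {
    "ihd": (0.152, 0.051),
    "ccf": (0.063, 0.009),
    "diabetes": (0.071, 0.020),
    "renal_disease": (0.055, 0.015),
}
_FRAC_MALE = (0.370, 0.473)

# relative days after onset on which an injured inpatient is re-tested
_AKI_RETEST_SCHEDULE = (0, 1, 2, 3, 5, 7, 10, 14, 21, 30)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class AdmissionParams:
    rate_per_year: float = 0.3
    mean_los_days: float = 5.0
    p_admit_at_onset: float = 0.8  # probability an AKI onset coincides with admission


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_patients: int = 500
    study_window: tuple[int, int] = STUDY_2003
    frac_abnormal_stratum: float = 0.6
    tests_per_year_shape: tuple[float, float] = (1.0, 2.0)  # gamma shape, scale
    # per-sex (log-median, log-sd) of baseline creatinine, μmol/L
    baseline_creatinine_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "male": (math.log(95.0), 0.25),
            "female": (math.log(75.0), 0.25),
        }
    )
    aki_incidence: float = 0.10
    # truncated log-normal over fold-rise ratios: (log-mean, log-sd, min ratio)
    aki_magnitude_dist: tuple[float, float, float] = (0.3, 0.4, 1.5)
    aki_onset_days: tuple[int, int] = (1, 3)  # uniform integer ramp duration
    aki_recovery_halflife: float = 5.0  # days
    coding_prob_by_stage: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.025, 2: 0.082, 3: 0.279}
    )
    false_coding_prob: float = 0.001
    frac_no_baseline: float = 0.08
    admission_gen_params: AdmissionParams = AdmissionParams()
    measurement_noise_cv: float = 0.05
    chronic_rrt_prob: float = 0.005

    def validate(self) -> None:
        probs = {
            "frac_abnormal_stratum": self.frac_abnormal_stratum,
            "aki_incidence": self.aki_incidence,
            "false_coding_prob": self.false_coding_prob,
            "frac_no_baseline": self.frac_no_baseline,
            "chronic_rrt_prob": self.chronic_rrt_prob,
            "admission_gen_params.p_admit_at_onset": self.admission_gen_params.p_admit_at_onset,
        }
        for stage, p in self.coding_prob_by_stage.items():
            probs[f"coding_prob_by_stage[{stage}]"] = p
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.n_patients < 0:
            raise ConfigurationError(f"n_patients must be >= 0, got {self.n_patients}")
        if self.study_window[0] > self.study_window[1]:
            raise ConfigurationError("study_window start must not exceed end")
        if self.aki_magnitude_dist[2] < 1.0:
            raise ConfigurationError(
                f"aki_magnitude_dist minimum ratio must be >= 1.0, "
                f"got {self.aki_magnitude_dist[2]}"
            )
        if self.aki_recovery_halflife <= 0:
            raise ConfigurationError(
                f"aki_recovery_halflife must be > 0, got {self.aki_recovery_halflife}"
            )
        if self.measurement_noise_cv < 0:
            raise ConfigurationError(
                f"measurement_noise_cv must be >= 0, got {self.measurement_noise_cv}"
            )
        if any(s <= 0 for s in self.tests_per_year_shape):
            raise ConfigurationError("tests_per_year_shape parameters must be positive")
        if self.aki_onset_days[0] < 0 or self.aki_onset_days[0] > self.aki_onset_days[1]:
            raise ConfigurationError(f"invalid aki_onset_days {self.aki_onset_days}")


def aki_factor(
    days: np.ndarray, onset_day: int, peak_ratio: float, onset_len: int, halflife: float
) -> np.ndarray:
    """Multiplicative excursion factor: linear ramp to the peak, then decay.

    Days before onset get factor 1; the factor reaches ``peak_ratio`` at
    ``onset_day + onset_len`` and afterwards relaxes back towards 1 with the
    given half-life.
    """
    if peak_ratio < 1.0:
        raise ValueError(f"peak_ratio must be >= 1.0, got {peak_ratio}")
    days = np.asarray(days, dtype=float)
    peak_day = onset_day + onset_len
    rel = days - onset_day
    if onset_len > 0:
        ramp = np.clip(rel / onset_len, 0.0, 1.0)
    else:
        ramp = (rel >= 0).astype(float)
    factor = 1.0 + (peak_ratio - 1.0) * ramp
    post = days > peak_day
    factor[post] = 1.0 + (peak_ratio - 1.0) * 0.5 ** ((days[post] - peak_day) / halflife)
    factor[rel < 0] = 1.0
    return factor


def inject_aki_episode(
    series: Sequence[CreatinineTest],
    onset_day: int,
    peak_ratio: float,
    onset_len: int,
    halflife: float,
) -> list[CreatinineTest]:
    """Apply an AKI excursion to an already-sorted creatinine series."""
    days = np.array([t.day for t in series])
    if len(days) > 1 and np.any(np.diff(days) < 0):
        raise ValueError("series must be sorted by day")
    factors = aki_factor(days, onset_day, peak_ratio, onset_len, halflife)
    return [
        replace(t, value=t.value * f) for t, f in zip(series, factors)
    ]


def _stage_from_ratio(ratio: float, peak_value: float, stage3_absolute: float = 354.0) -> int:
    if ratio >= 3.0 or (ratio >= 1.5 and peak_value > stage3_absolute):
        return 3
    if ratio >= 2.0:
        return 2
    if ratio >= 1.5:
        return 1
    return 0


def _baseline_for_stratum(
    rng: np.random.Generator, sex: str, age: float, abnormal: bool,
    params: Mapping[str, tuple[float, float]],
) -> float:
    """Sample a baseline creatinine conditioned on the eGFR stratum."""
    mu, sigma = params[sex]
    # creatinine at the eGFR = 60 boundary for this patient
    female = 0.742 if sex == "female" else 1.0
    boundary = 88.4 * (60.0 / (175.0 * age**-0.203 * female)) ** (1.0 / -1.154)
    for _ in range(200):
        value = float(rng.lognormal(mu, sigma))
        egfr = mdrd_egfr(value, age, sex)
        if abnormal == (egfr < 60.0):
            return value
    return boundary * (1.05 if abnormal else 0.95)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (tests, patients, truth) tables for one synthetic cohort.

    Tests span one year before the study window to thirty days after it, so
    look-back references and the retrospective (future-minimum) criterion
    both have material to work with. Patients with an injected episode carry
    a repeat-testing schedule after onset, mimicking inpatient monitoring.
    """
    config.validate()
    lo, hi = config.study_window
    span_lo, span_hi = lo - 365, hi + 30
    span_years = (span_hi - span_lo) / 365.0
    adm = config.admission_gen_params
    log_mu, log_sd, min_ratio = config.aki_magnitude_dist
    noise_sigma = (
        math.sqrt(math.log(1.0 + config.measurement_noise_cv**2))
        if config.measurement_noise_cv > 0
        else 0.0
    )

    test_rows: list[tuple] = []
    patient_rows: list[dict] = []
    truth_rows: list[dict] = []

    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"P{i:06d}"
        abnormal = rng.random() < config.frac_abnormal_stratum
        col = 0 if abnormal else 1
        sex = "male" if rng.random() < _FRAC_MALE[col] else "female"
        age = float(np.clip(rng.normal(74, 10) if abnormal else rng.normal(53, 16), 15, 99))
        baseline = _baseline_for_stratum(
            rng, sex, age, abnormal, config.baseline_creatinine_params
        )
        flags = {
            name: bool(rng.random() < prev[col])
            for name, prev in _COMORBIDITY_PREV.items()
        }
        chronic_rrt = bool(rng.random() < config.chronic_rrt_prob)

        # background testing: heterogeneous per-patient Poisson process
        shape, scale = config.tests_per_year_shape
        rate = rng.gamma(shape, scale)
        n_bg = rng.poisson(rate * span_years)
        days = set(rng.integers(span_lo, span_hi + 1, size=n_bg).tolist())

        # background admissions with clustered inpatient testing
        admissions: list[tuple[int, int]] = []
        for _ in range(rng.poisson(adm.rate_per_year * span_years)):
            admit = int(rng.integers(span_lo, span_hi))
            los = max(1, int(round(rng.lognormal(math.log(adm.mean_los_days), 0.5))))
            admissions.append((admit, min(admit + los, span_hi + 1)))
        for admit, discharge in admissions:
            for d in range(admit, discharge):
                if rng.random() < 0.5:
                    days.add(d)

        # AKI injection
        true_aki = rng.random() < config.aki_incidence
        onset_day = peak_ratio = onset_len = None
        no_baseline = False
        if true_aki:
            peak_ratio = max(float(rng.lognormal(log_mu, log_sd)), min_ratio)
            onset_len = int(rng.integers(config.aki_onset_days[0], config.aki_onset_days[1] + 1))
            # the ramp peaks inside the study window: this is a study-year episode
            onset_day = int(rng.integers(lo, max(lo, hi - onset_len) + 1))
            for rel in _AKI_RETEST_SCHEDULE:
                if rel == onset_len or rng.random() < 0.8:
                    d = onset_day + rel
                    if d <= span_hi:
                        days.add(d)
            # guarantee a usable look-back reference unless deliberately absent
            no_baseline = rng.random() < config.frac_no_baseline
            if not no_baseline and not any(
                onset_day - 355 <= d <= onset_day - 8 for d in days
            ):
                days.add(onset_day - int(rng.integers(10, 300)))
            if rng.random() < adm.p_admit_at_onset:
                los = max(
                    3, int(round(rng.lognormal(math.log(adm.mean_los_days), 0.5)))
                )
                admissions.append((onset_day, min(onset_day + los, span_hi + 1)))

        day_arr = np.array(sorted(d for d in days if span_lo <= d <= span_hi), dtype=np.int64)
        values = np.full(len(day_arr), baseline)
        if true_aki and len(day_arr):
            values = values * aki_factor(
                day_arr, onset_day, peak_ratio, onset_len, config.aki_recovery_halflife
            )
        if no_baseline and onset_day is not None:
            # patient presents with established AKI: nothing before the peak
            keep = day_arr >= onset_day + onset_len
            day_arr, values = day_arr[keep], values[keep]
        if noise_sigma > 0 and len(values):
            values = values * rng.lognormal(0.0, noise_sigma, size=len(values))
        values = np.round(values, 1)

        admissions = sorted(admissions)
        for d, v in zip(day_arr.tolist(), values.tolist()):
            setting = (
                "inpatient"
                if any(a <= d < b for a, b in admissions)
                else "community"
            )
            test_rows.append((pid, d, v, setting))

        # coding: stage-dependent for true episodes, small false-coding rate otherwise
        if true_aki:
            true_stage = _stage_from_ratio(peak_ratio, baseline * peak_ratio)
            p_code = config.coding_prob_by_stage.get(true_stage, config.false_coding_prob)
        else:
            true_stage = 0
            p_code = config.false_coding_prob
        coded = bool(rng.random() < p_code)

        has_baseline = bool(
            true_aki
            and any(onset_day - 365 <= d <= onset_day - 1 for d in day_arr.tolist())
        )
        patient_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "age": round(age, 1),
                **flags,
                "chronic_rrt": chronic_rrt,
                "admissions": admissions,
                "coded_aki": coded,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "true_aki": true_aki,
                "true_onset_day": onset_day if true_aki else pd.NA,
                "true_peak_ratio": round(peak_ratio, 4) if true_aki else pd.NA,
                "true_stage": true_stage,
                "coded": coded,
                "has_baseline_in_year": has_baseline,
            }
        )

    tests = pd.DataFrame(
        test_rows, columns=["patient_id", "day", "value", "setting"]
    )
    patients = pd.DataFrame(
        patient_rows,
        columns=[
            "patient_id", "sex", "age", "ihd", "ccf", "diabetes",
            "renal_disease", "chronic_rrt", "admissions", "coded_aki",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "true_aki", "true_onset_day", "true_peak_ratio",
            "true_stage", "coded", "has_baseline_in_year",
        ],
    )
    return tests, patients, truth
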