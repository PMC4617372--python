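"""Canonical longitudinal creatinine data model.

Serum-creatinine series are held at whole-day resolution: every test carries
an integer day (a proleptic Gregorian ordinal, ``datetime.date.toordinal``),
a value in μmol/L and a care setting. Operations here prepare a raw extract
for alerting: per-day deduplication (the alerting convention keeps the
highest creatinine on each day), exclusion of chronic renal-replacement
patients, retrospective/prospective window extraction, and the four-variable
MDRD eGFR used to describe baseline kidney function.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SETTINGS = ("inpatient", "community", "unknown")

TEST_COLUMNS = ["patient_id", "day", "value", "setting"]


class ValidationError(ValueError):
    """Raised when input records violate the data contract."""


def day_number(date: str | _dt.date) -> int:
    """Whole-day representation of a calendar date (proleptic ordinal)."""
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return date.toordinal()


def day_to_date(day: int) -> _dt.date:
    return _dt.date.fromordinal(int(day))


@dataclass(frozen=True)
class CreatinineTest:
    """One laboratory serum-creatinine measurement."""

    patient_id: str
    day: int
    value: float  # μmol/L, > 0
    setting: str = "unknown"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(
                f"creatinine must be positive, got {self.value!r} "
                f"(patient {self.patient_id}, day {self.day})"
            )
        if self.setting not in SETTINGS:
            raise ValidationError(f"unknown setting {self.setting!r}")


@dataclass
class PatientRecord:
    """Demographics, comorbidity flags and linkage labels for one patient."""

    patient_id: str
    sex: str  # "male" | "female"
    age: float  # years at study start; adult cohort, >= 15
    ihd: bool = False
    ccf: bool = False
    diabetes: bool = False
    renal_disease: bool = False
    chronic_rrt: bool = False
    admissions: list[tuple[int, int]] = field(default_factory=list)  # [admit, discharge)
    coded_aki: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.age < 15:
            raise ValidationError(
                f"adult cohort: age must be >= 15, got {self.age} "
                f"(patient {self.patient_id})"
            )
        for admit, discharge in self.admissions:
            if not admit < discharge:
                raise ValidationError(
                    f"degenerate admission [{admit}, {discharge}) for "
                    f"patient {self.patient_id}"
                )


def tests_to_frame(tests: Iterable[CreatinineTest]) -> pd.DataFrame:
    rows = [(t.patient_id, t.day, t.value, t.setting) for t in tests]
    return pd.DataFrame(rows, columns=TEST_COLUMNS)


def frame_to_tests(frame: pd.DataFrame) -> list[CreatinineTest]:
    return [
        CreatinineTest(str(r.patient_id), int(r.day), float(r.value), str(r.setting))
        for r in frame.itertuples(index=False)
    ]


def dedup_daily_max(tests: pd.DataFrame, mode: str = "daily_max") -> pd.DataFrame:
    """Collapse repeat same-day samples.

    The alerting convention keeps the highest creatinine per (patient, day),
    preventing spurious low samples from generating false alerts. The
    ``keep_all`` mode passes every record through — the sensitivity-analysis
    variant in which all results are included.

    Output is sorted by patient then day.
    """
    if mode not in ("daily_max", "keep_all"):
        raise ValueError(f"mode must be 'daily_max' or 'keep_all', got {mode!r}")
    bad = tests[tests["value"] <= 0]
    if len(bad):
        raise ValidationError(
            "non-positive creatinine values at rows "
            + ", ".join(str(i) for i in bad.index[:20])
        )
    if mode == "keep_all":
        out = tests.sort_values(["patient_id", "day"], kind="stable")
    else:
        out = (
            tests.sort_values(["patient_id", "day", "value"], kind="stable")
            .groupby(["patient_id", "day"], as_index=False, sort=True)
            .last()
        )
        out = out[tests.columns.tolist()]
    return out.reset_index(drop=True)


def exclude_chronic_rrt(
    patients: pd.DataFrame, tests: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop patients on chronic renal replacement therapy and all their tests.

    Chronic dialysis/transplant patients have creatinine dynamics that would
    otherwise be misclassified as acute injury.
    """
    flagged = set(patients.loc[patients["chronic_rrt"].astype(bool), "patient_id"])
    kept_patients = patients[~patients["patient_id"].isin(flagged)].reset_index(drop=True)
    kept_tests = tests[~tests["patient_id"].isin(flagged)].reset_index(drop=True)
    logger.info(
        "chronic RRT exclusion: removed %d patients, %d tests",
        len(patients) - len(kept_patients),
        len(tests) - len(kept_tests),
    )
    return kept_patients, kept_tests


def window_values(
    days: Sequence[int] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    index_day: int,
    offset_lo: int,
    offset_hi: int,
) -> np.ndarray:
    """Values of tests with day in [index_day - offset_hi, index_day - offset_lo].

    Both bounds inclusive. Positive offsets look back (``offset_lo=8,
    offset_hi=365`` is the 8–365-days-ago window); negative offsets address
    the future (``offset_lo=-30, offset_hi=-1`` is the 30 days after the
    index). The index day itself is excluded whenever offset_lo >= 1. An
    empty window (offset_lo > offset_hi) yields an empty array.

    ``days`` must be sorted ascending; a contract violation is raised
    otherwise.
    """
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    if len(days) > 1 and np.any(np.diff(days) < 0):
        raise ValidationError("window_values requires days sorted ascending")
    if offset_lo > offset_hi:
        return values[:0]
    lo = index_day - offset_hi
    hi = index_day - offset_lo
    i = np.searchsorted(days, lo, side="left")
    j = np.searchsorted(days, hi, side="right")
    return values[i:j]


@dataclass(frozen=True)
class EgfrParams:
    """Constants of the four-variable MDRD equation (creatinine in μmol/L)."""

    constant: float = 175.0
    creatinine_exponent: float = -1.154
    age_exponent: float = -0.203
    female_factor: float = 0.742
    creatinine_unit_divisor: float = 88.4  # μmol/L per mg/dL


def mdrd_egfr(
    value: float | np.ndarray,
    age: float | np.ndarray,
    sex: str | np.ndarray,
    params: EgfrParams = EgfrParams(),
) -> float | np.ndarray:
    """Four-variable MDRD estimated GFR, mL/min/1.73m².

    175 × (SCr/88.4)^−1.154 × age^−0.203 × 0.742 (if female). No ethnicity
    term is applied (no ethnicity field is modelled in this cohort); override
    ``params`` to change any coefficient.
    """
    value = np.asarray(value, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(value <= 0):
        raise ValueError("creatinine must be positive")
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    female = np.asarray(sex) == "female"
    egfr = (
        params.constant
        * (value / params.creatinine_unit_divisor) ** params.creatinine_exponent
        * age**params.age_exponent
        * np.where(female, params.female_factor, 1.0)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr
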