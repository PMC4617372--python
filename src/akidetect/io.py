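"""File formats, configuration and the end-to-end pipeline.

The interchange format is plain CSV with explicit headers — routine
biochemistry extracts are tabular, and nothing here needs more. Three input
tables drive the pipeline:

``tests.csv``       patient_id, date (ISO 8601), creatinine_umol_l[, setting]
``patients.csv``    patient_id, sex, age, ihd, ccf, diabetes, renal_disease,
                    chronic_rrt, coded_aki
``admissions.csv``  patient_id, admit_date, discharge_date  (half-open)

Dates are parsed to whole-day ordinals internally. Validation errors name
the offending row. ``run_pipeline`` composes parsing → deduplication → RRT
exclusion → detection → evaluation deterministically, logging counts at
each stage.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import detector, evaluation, timeline
from .timeline import ValidationError, day_number, day_to_date

logger = logging.getLogger(__name__)

_BOOL_COLS = ["ihd", "ccf", "diabetes", "renal_disease", "chronic_rrt", "coded_aki"]


def _parse_date(raw: str, row: int, path: str) -> int:
    try:
        return day_number(str(raw))
    except ValueError:
        raise ValidationError(f"{path}: row {row}: unparseable date {raw!r}")


def read_tests(path: str | Path) -> pd.DataFrame:
    """Read and validate a creatinine test table."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "date", "creatinine_umol_l"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    days = [
        _parse_date(d, i + 2, str(path)) for i, d in enumerate(frame["date"])
    ]
    values = pd.to_numeric(frame["creatinine_umol_l"], errors="coerce")
    bad = values.isna() | (values <= 0)
    if bad.any():
        rows = [i + 2 for i in frame.index[bad][:10]]
        raise ValidationError(
            f"{path}: non-positive or unreadable creatinine at rows {rows}"
        )
    setting = (
        frame["setting"] if "setting" in frame.columns else "unknown"
    )
    out = pd.DataFrame(
        {
            "patient_id": frame["patient_id"],
            "day": days,
            "value": values.astype(float),
            "setting": setting,
        }
    )
    logger.info("%s: read %d tests for %d patients", path, len(out), out["patient_id"].nunique())
    return out


def read_patients(path: str | Path, admissions_path: str | Path | None = None) -> pd.DataFrame:
    """Read the patient table, attaching admission intervals when present."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "sex", "age"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if frame["patient_id"].duplicated().any():
        rows = [i + 2 for i in frame.index[frame["patient_id"].duplicated()][:10]]
        raise ValidationError(f"{path}: duplicate patient_id at rows {rows}")
    bad_sex = ~frame["sex"].isin(["male", "female"])
    if bad_sex.any():
        rows = [i + 2 for i in frame.index[bad_sex][:10]]
        raise ValidationError(f"{path}: sex must be male/female at rows {rows}")
    if (frame["age"] < 15).any():
        rows = [i + 2 for i in frame.index[frame["age"] < 15][:10]]
        raise ValidationError(f"{path}: adult cohort requires age >= 15 at rows {rows}")
    for col in _BOOL_COLS:
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
        else:
            frame[col] = False

    admissions: dict[str, list[tuple[int, int]]] = {pid: [] for pid in frame["patient_id"]}
    if admissions_path is not None and Path(admissions_path).exists():
        adm = pd.read_csv(admissions_path, dtype={"patient_id": str})
        for i, row in enumerate(adm.itertuples(index=False)):
            a = _parse_date(row.admit_date, i + 2, str(admissions_path))
            d = _parse_date(row.discharge_date, i + 2, str(admissions_path))
            if not a < d:
                raise ValidationError(
                    f"{admissions_path}: row {i + 2}: degenerate admission "
                    f"[{row.admit_date}, {row.discharge_date})"
                )
            admissions.setdefault(str(row.patient_id), []).append((a, d))
    frame["admissions"] = [sorted(admissions.get(pid, [])) for pid in frame["patient_id"]]
    logger.info("%s: read %d patients", path, len(frame))
    return frame


def write_tests(tests: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "patient_id": tests["patient_id"],
            "date": [day_to_date(d).isoformat() for d in tests["day"]],
            "creatinine_umol_l": tests["value"],
            "setting": tests["setting"],
        }
    )
    out.to_csv(path, index=False)


def write_patients(
    patients: pd.DataFrame, path: str | Path, admissions_path: str | Path | None = None
) -> None:
    cols = ["patient_id", "sex", "age"] + [c for c in _BOOL_COLS if c in patients.columns]
    patients[cols].to_csv(path, index=False)
    if admissions_path is not None and "admissions" in patients.columns:
        rows = [
            (pid, day_to_date(a).isoformat(), day_to_date(d).isoformat())
            for pid, intervals in zip(patients["patient_id"], patients["admissions"])
            for a, d in intervals
        ]
        pd.DataFrame(rows, columns=["patient_id", "admit_date", "discharge_date"]).to_csv(
            admissions_path, index=False
        )


@dataclass
class PipelineConfig:
    """Everything the detect/evaluate pipeline needs, file paths included."""

    study_window: tuple[int, int]
    model_id: str = "A"
    criterion3_window_days: int = 2
    dedup_mode: str = "daily_max"
    ci_method: str = "clopper-pearson"
    adult_upper_reference: Mapping[str, float] = field(
        default_factory=lambda: {"female": 110.0, "male": 120.0}
    )
    suppression_threshold: int = 5
    tests_path: str = "tests.csv"
    patients_path: str = "patients.csv"
    admissions_path: str | None = "admissions.csv"
    seed: int = 0

    _KNOWN = {
        "study_window", "model_id", "criterion3_window_days", "dedup_mode",
        "ci_method", "adult_upper_reference", "suppression_threshold",
        "tests_path", "patients_path", "admissions_path", "seed",
    }

    def __post_init__(self) -> None:
        if self.model_id.upper() not in detector.MODELS:
            raise ValidationError(f"model_id must be one of A-D, got {self.model_id!r}")
        if self.criterion3_window_days not in (1, 2):
            raise ValidationError("criterion3_window_days must be 1 or 2")
        if self.dedup_mode not in ("daily_max", "keep_all"):
            raise ValidationError(f"unknown dedup_mode {self.dedup_mode!r}")
        if self.ci_method not in ("clopper-pearson", "wilson"):
            raise ValidationError(f"unknown ci_method {self.ci_method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "study_window" in raw:
            lo, hi = raw["study_window"]
            raw["study_window"] = (day_number(str(lo)), day_number(str(hi)))
        if "study_window" not in raw:
            raise ValidationError("config must set study_window")
        return cls(**raw)

    def detector_config(self) -> detector.DetectorConfig:
        staging = detector.StagingRules(
            adult_upper_reference=dict(self.adult_upper_reference)
        )
        return detector.DetectorConfig(
            study_window=self.study_window,
            criterion3_window_days=self.criterion3_window_days,
            staging=staging,
        )


def run_pipeline(config: PipelineConfig) -> evaluation.EvaluationReport:
    """Parse inputs, detect under the configured model, evaluate vs coded AKI."""
    tests = read_tests(config.tests_path)
    patients = read_patients(config.patients_path, config.admissions_path)
    tests = timeline.dedup_daily_max(tests, mode=config.dedup_mode)
    logger.info("after dedup (%s): %d tests", config.dedup_mode, len(tests))
    patients, tests = timeline.exclude_chronic_rrt(patients, tests)
    episodes, alerts, flags = detector.detect_cohort(
        tests, patients, config.model_id, config.detector_config()
    )
    logger.info(
        "model %s: %d alerts, %d episodes, %d flags",
        config.model_id, len(alerts), len(episodes), len(flags),
    )
    report = evaluation.evaluate_models(
        {config.model_id: episodes}, patients,
        reference_label=config.model_id, ci_method=config.ci_method,
    )
    report.stage_table = evaluation.stage_stratified_table(episodes, patients)
    report.n_flags = len(flags)
    return report
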