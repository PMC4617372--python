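import numpy as np
import pandas as pd
import pytest

from akidetect import timeline
from akidetect.detector import DetectorConfig
from akidetect.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=42, n_patients=500)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One deduplicated synthetic cohort shared across read-only tests."""
    tests, patients, truth = simulate_cohort(default_config)
    tests = timeline.dedup_daily_max(tests)
    return tests, patients, truth


@pytest.fixture(scope="session")
def detector_config(default_config) -> DetectorConfig:
    return DetectorConfig(study_window=default_config.study_window)


def make_tests(records, patient_id="P1") -> pd.DataFrame:
    """Tests table from (day, value) or (patient, day, value) tuples."""
    rows = []
    for rec in records:
        if len(rec) == 2:
            rows.append((patient_id, rec[0], rec[1], "unknown"))
        else:
            rows.append((rec[0], rec[1], rec[2], "unknown"))
    return pd.DataFrame(rows, columns=["patient_id", "day", "value", "setting"])


def make_patients(ids, **overrides) -> pd.DataFrame:
    base = {
        "sex": "male",
        "age": 60.0,
        "ihd": False,
        "ccf": False,
        "diabetes": False,
        "renal_disease": False,
        "chronic_rrt": False,
        "coded_aki": False,
    }
    rows = []
    for pid in ids:
        row = {"patient_id": pid, **base}
        for key, val in overrides.items():
            row[key] = val[pid] if isinstance(val, dict) else val
        row.setdefault("admissions", [])
        if "admissions" not in overrides:
            row["admissions"] = []
        rows.append(row)
    columns = [
        "patient_id", "sex", "age", "ihd", "ccf", "diabetes", "renal_disease",
        "chronic_rrt", "coded_aki", "admissions",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    if "admissions" in overrides:
        frame["admissions"] = [
            overrides["admissions"].get(pid, []) if isinstance(overrides["admissions"], dict)
            else overrides["admissions"]
            for pid in ids
        ]
    return frame
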