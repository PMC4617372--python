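"""Shared cohort settings for the numbered analysis scripts.

One synthetic cohort (seed 42, 2000 patients, generator defaults) is used
throughout; script 01 materialises it under scratch/cohort and later
scripts regenerate it in memory if the files are absent.
"""

from pathlib import Path

from akidetect import io, timeline
from akidetect.synthetic import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

COHORT_CONFIG = SimulationConfig(seed=42, n_patients=2000)


def load_or_simulate():
    """(tests, patients, truth), deduplicated and RRT-excluded."""
    import pandas as pd

    if (SCRATCH / "tests.csv").exists():
        tests = io.read_tests(SCRATCH / "tests.csv")
        patients = io.read_patients(SCRATCH / "patients.csv", SCRATCH / "admissions.csv")
        truth = pd.read_csv(SCRATCH / "truth.csv", dtype={"patient_id": str})
    else:
        tests, patients, truth = simulate_cohort(COHORT_CONFIG)
    tests = timeline.dedup_daily_max(tests)
    patients, tests = timeline.exclude_chronic_rrt(patients, tests)
    return tests, patients, truth
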