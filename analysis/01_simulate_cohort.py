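"""Simulate the working synthetic cohort and summarise its structure.

Writes the pipeline input tables under scratch/cohort/ and a small
structural summary (strata, testing intensity, injected-episode mix) to
results/cohort_summary.csv.
"""

import pandas as pd

from akidetect import io, timeline
from akidetect.synthetic import simulate_cohort

from _cohort import COHORT_CONFIG, RESULTS, SCRATCH


def main() -> None:
    tests, patients, truth = simulate_cohort(COHORT_CONFIG)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    io.write_tests(tests, SCRATCH / "tests.csv")
    io.write_patients(patients, SCRATCH / "patients.csv", SCRATCH / "admissions.csv")
    truth.to_csv(SCRATCH / "truth.csv", index=False)

    lo, hi = COHORT_CONFIG.study_window
    in_year = tests[tests["day"].between(lo, hi)]
    tests_per_patient = in_year.groupby("patient_id").size()
    first = tests.sort_values("day").groupby("patient_id").first().reset_index()
    merged = first.merge(patients, on="patient_id")
    egfr = timeline.mdrd_egfr(
        merged["value"].to_numpy(), merged["age"].to_numpy(), merged["sex"].to_numpy()
    )
    summary = pd.DataFrame(
        {
            "quantity": [
                "patients", "tests_total", "tests_in_study_year",
                "median_tests_per_tested_patient", "frac_abnormal_egfr",
                "true_aki_patients", "coded_patients", "chronic_rrt_patients",
                "aki_without_baseline",
            ],
            "value": [
                len(patients), len(tests), len(in_year),
                float(tests_per_patient.median()), float((egfr < 60).mean()),
                int(truth["true_aki"].sum()), int(truth["coded"].sum()),
                int(patients["chronic_rrt"].sum()),
                int((truth["true_aki"] & ~truth["has_baseline_in_year"]).sum()),
            ],
        }
    )
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\ncohort written to {SCRATCH}")


if __name__ == "__main__":
    main()
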