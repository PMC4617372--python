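"""Recompute the published headline statistics from their validation counts.

The regional cohort behind the published validation is not distributable,
but every headline statistic is a deterministic function of printed counts:
detected/coded patients per model, and first-episode counts over the adult
population. Feeding those counts through the evaluation operations
reproduces the published sensitivities (with exact binomial intervals) and
incidence rates; the table goes to results/headline_statistics.csv.
"""

import pandas as pd

from akidetect.evaluation import incidence_pmp, sensitivity_ci

from _cohort import RESULTS

N_CODED = 329
POPULATION = 438_332


def main() -> None:
    rows = []
    for label, detected in [
        ("model_A (criteria 1-3)", 300),
        ("criteria_2_3_only", 244),
        ("model_B (+retrospective)", N_CODED - 16),
        ("model_D (all criteria)", N_CODED - 11),
    ]:
        r = sensitivity_ci(detected, N_CODED)
        rows.append(
            {
                "statistic": f"sensitivity {label}",
                "value": r.sensitivity,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n": N_CODED,
            }
        )
    for label, n_aki in [("model_A", 5565), ("model_D", 10811)]:
        r = incidence_pmp(n_aki, POPULATION)
        rows.append(
            {
                "statistic": f"incidence_pmp {label}",
                "value": r.rate_pmp,
                "ci_low": None,
                "ci_high": None,
                "n": POPULATION,
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "headline_statistics.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
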