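"""Validation analysis: sensitivity against coded AKI, staging tables, incidence.

Sensitivity is the proportion of reference-standard positives (patients with
a coded AKI discharge diagnosis) that a biochemical detection model alerts
on, with an exact binomial (Clopper–Pearson) 95% confidence interval by
default (Wilson available). Coded diagnoses are a highly specific subset of
AKI, so only sensitivity is reported against them — specificity, PPV and
ROC analysis are deliberately unavailable against coded labels and are left
to synthetic ground truth, where the full truth is known.

Percentages are rounded half-up to one decimal place, incidence rates
half-up to the nearest integer per million population, matching routine
epidemiological reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .detector import AkiEpisode
from .timeline import ValidationError


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (122.5 -> 123), as used in printed tables."""
    x = float(x)
    if x != x:  # NaN passes through
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SensitivityResult:
    n_reference_positive: int
    n_detected: int
    sensitivity: float  # percentage, 1 dp
    ci_low: float  # percentage, 1 dp
    ci_high: float  # percentage, 1 dp
    method_label: str


def sensitivity_ci(
    n_detected: int, n_positive: int, method: str = "clopper-pearson"
) -> SensitivityResult:
    """Sensitivity with a 95% binomial confidence interval.

    ``method`` is ``"clopper-pearson"`` (exact, default) or ``"wilson"``.
    """
    if n_positive < 1:
        raise ValidationError("sensitivity undefined: zero reference positives")
    if not 0 <= n_detected <= n_positive:
        raise ValidationError(
            f"need 0 <= n_detected <= n_positive, got ({n_detected}, {n_positive})"
        )
    sm_method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(n_detected, n_positive, alpha=0.05, method=sm_method)
    return SensitivityResult(
        n_reference_positive=n_positive,
        n_detected=n_detected,
        sensitivity=round_half_up(100.0 * n_detected / n_positive, 1),
        ci_low=round_half_up(100.0 * float(lo), 1),
        ci_high=round_half_up(100.0 * float(hi), 1),
        method_label=method,
    )


@dataclass(frozen=True)
class IncidenceResult:
    n_aki_patients: int
    population: int
    rate_pmp: int  # per million population per year


def incidence_pmp(n_aki_patients: int, population: int) -> IncidenceResult:
    """First-episode incidence per million population per year."""
    if population <= 0:
        raise ValidationError("population must be positive")
    rate = round_half_up(n_aki_patients / population * 1_000_000, 0)
    return IncidenceResult(n_aki_patients, population, int(rate))


@dataclass
class EvaluationReport:
    """Per-criterion and per-model sensitivity plus descriptor tables."""

    rows: pd.DataFrame  # label, n_alerted, n_detected, n_positive, sensitivity, ci
    missed: pd.DataFrame  # coded patients not alerted by the reference model
    detected: pd.DataFrame
    stage_table: pd.DataFrame | None = None
    incidence: IncidenceResult | None = None
    n_flags: int = 0


_DESCRIPTOR_COLS = ["patient_id", "sex", "age", "ihd", "ccf", "diabetes", "renal_disease"]


def evaluate_models(
    episodes_by_label: Mapping[str, Sequence[AkiEpisode]],
    patients: pd.DataFrame,
    reference_label: str = "A",
    ci_method: str = "clopper-pearson",
) -> EvaluationReport:
    """Sensitivity of each detection model/criterion against coded AKI.

    ``episodes_by_label`` maps a label (a model id or a single-criterion
    label) to the patient-level episodes it produced on one common cohort.
    The report lists, per label, the alerted-patient count and sensitivity
    with CI; coded patients missed by ``reference_label`` are profiled with
    their descriptors.
    """
    coded = set(patients.loc[patients["coded_aki"].astype(bool), "patient_id"])
    universe = set(patients["patient_id"])
    n_positive = len(coded)

    rows = []
    for label, episodes in episodes_by_label.items():
        alerted = {e.patient_id for e in episodes}
        if not alerted <= universe:
            raise ValidationError(
                f"episodes for {label!r} reference patients outside the cohort"
            )
        detected = len(alerted & coded)
        if n_positive:
            s = sensitivity_ci(detected, n_positive, ci_method)
            sens, lo, hi = s.sensitivity, s.ci_low, s.ci_high
        else:
            sens = lo = hi = float("nan")
        rows.append(
            {
                "label": label,
                "n_alerted": len(alerted),
                "n_detected": detected,
                "n_positive": n_positive,
                "sensitivity_pct": sens,
                "ci_low_pct": lo,
                "ci_high_pct": hi,
                "ci_method": ci_method,
            }
        )
    report_rows = pd.DataFrame(rows)

    ref_alerted = {e.patient_id for e in episodes_by_label.get(reference_label, [])}
    cols = [c for c in _DESCRIPTOR_COLS if c in patients.columns]
    missed = patients[patients["patient_id"].isin(coded - ref_alerted)][cols]
    detected_df = patients[patients["patient_id"].isin(coded & ref_alerted)][cols]
    return EvaluationReport(
        rows=report_rows,
        missed=missed.reset_index(drop=True),
        detected=detected_df.reset_index(drop=True),
    )


def stage_stratified_table(
    episodes: Sequence[AkiEpisode], patients: pd.DataFrame
) -> pd.DataFrame:
    """Descriptors of alerted patients stratified by peak AKI stage.

    One column per peak stage (1–3) plus the pooled "any" column: patient
    count, coded-AKI count and percentage, median (IQR) alerts received,
    community/inpatient split at first alert, recency of the previous test
    (within vs beyond 2 and 7 days), and the count whose peak reached Stage
    3 after a lower stage at first detection.
    """
    coded = set(patients.loc[patients["coded_aki"].astype(bool), "patient_id"])
    frame = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in episodes],
            "peak_stage": [e.peak_stage_within_30d for e in episodes],
            "first_stage": [e.stage_at_first_detection for e in episodes],
            "n_alerts": [e.n_alerts for e in episodes],
            "community": [e.location_at_first_alert == "community" for e in episodes],
            "days_since_prev": [
                e.days_since_previous_test_at_first_alert for e in episodes
            ],
        }
    )
    frame["coded"] = frame["patient_id"].isin(coded)

    def summarise(sub: pd.DataFrame) -> dict:
        n = len(sub)
        if n == 0:
            return {"n": 0}
        q25, med, q75 = sub["n_alerts"].quantile([0.25, 0.5, 0.75])
        prev = sub["days_since_prev"].dropna()
        n_coded = int(sub["coded"].sum())
        n_comm = int(sub["community"].sum())
        return {
            "n": n,
            "coded_aki": n_coded,
            "coded_aki_pct": round_half_up(100 * n_coded / n, 1),
            "alerts_median": med,
            "alerts_q25": q25,
            "alerts_q75": q75,
            "community_pct": round_half_up(100 * n_comm / n, 1),
            "inpatient_pct": round_half_up(100 * (n - n_comm) / n, 1),
            "first_alert_gt2d_pct": round_half_up(
                100 * float((prev > 2).mean()) if len(prev) else float("nan"), 1
            ),
            "first_alert_gt7d_pct": round_half_up(
                100 * float((prev > 7).mean()) if len(prev) else float("nan"), 1
            ),
            "progressed_to_stage3": int(
                ((sub["peak_stage"] == 3) & (sub["first_stage"] < 3)).sum()
            ),
        }

    out = {}
    for stage in (1, 2, 3):
        out[f"stage_{stage}"] = summarise(frame[frame["peak_stage"] == stage])
    out["any"] = summarise(frame)
    return pd.DataFrame(out)


def suppress_small_cells(
    table: pd.DataFrame, threshold: int = 5, zero_exempt: bool = True
) -> pd.DataFrame:
    """Mask small counts for disclosure control.

    Integer counts below ``threshold`` are rendered as ``"<threshold"``;
    zeros are exempt by default. Percentage columns paired with a masked
    count (same prefix, ``_pct`` suffix) are masked too.
    """
    out = table.copy().astype(object)
    masked_positions: list[tuple] = []
    for col in out.columns:
        for idx in out.index:
            v = out.at[idx, col]
            if (
                isinstance(v, (int, np.integer))
                and not isinstance(v, (bool, np.bool_))
                and 0 <= v < threshold
            ):
                if zero_exempt and v == 0:
                    continue
                out.at[idx, col] = f"<{threshold}"
                masked_positions.append((idx, col))
    # mask percentages derived from suppressed counts (row-oriented tables)
    for idx, col in masked_positions:
        pct_col = f"{col}_pct"
        if pct_col in out.columns:
            out.at[idx, pct_col] = "-"
        if isinstance(idx, str):
            pct_idx = f"{idx}_pct"
            if pct_idx in out.index:
                out.at[pct_idx, col] = "-"
    return out


def detection_vs_truth(
    episodes: Sequence[AkiEpisode], truth: pd.DataFrame
) -> dict[str, float]:
    """Detection metrics against synthetic ground truth (truth fully known).

    Returns sensitivity/specificity/PPV as proportions in [0, 1]; available
    only for simulated cohorts where every true episode is known.
    """
    alerted = {e.patient_id for e in episodes}
    pos = set(truth.loc[truth["true_aki"].astype(bool), "patient_id"])
    neg = set(truth["patient_id"]) - pos
    tp = len(alerted & pos)
    fp = len(alerted & neg)
    return {
        "sensitivity": tp / len(pos) if pos else float("nan"),
        "specificity": (len(neg) - fp) / len(neg) if neg else float("nan"),
        "ppv": tp / len(alerted) if alerted else float("nan"),
        "n_true_aki": len(pos),
        "n_detected_true": tp,
    }
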