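"""AKI e-alert detection: criteria 1–6, detection models A–D, staging.

The national automated algorithm compares each new (index) serum creatinine
with reference values derived from the patient's own series:

=========  ==============  =============================  ==============
criterion  window           reference                      trigger
=========  ==============  =============================  ==============
1          8–365 days ago  median of window               ratio >= 1.5
2          1–7 days ago    lowest in window               ratio >= 1.5
3          48 h (2 days)   lowest in window               rise > 26 μmol/L
4          30 days after   lowest in window (future)      ratio >= 1.5
5          3 years ago     most recent in window          ratio >= 1.5
6          8–365 days ago  lowest in window               ratio >= 1.5
=========  ==============  =============================  ==============

Criteria 1–3 form the deployed algorithm (model A); criteria 4–6 are
research extensions added incrementally (models B, C, D). Staging follows
the KDIGO creatinine bands: Stage 1 for a rise > 26 μmol/L or ratio in
[1.5, 2); Stage 2 for ratio in [2, 3); Stage 3 for ratio >= 3 or a ratio
>= 1.5 with an index above 354 μmol/L (three times the upper reference
interval under 18). When several references are available, the one giving
the highest stage is used.

All comparisons run at whole-day resolution: "48 h" is the previous 1–2
days, configurable down to 1 day for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .timeline import ValidationError, window_values

logger = logging.getLogger(__name__)

RATIO_THRESHOLD = 1.5
RISE_THRESHOLD = 26.0  # μmol/L, strict inequality


@dataclass(frozen=True)
class CriterionRule:
    criterion_id: int
    offset_lo: int
    offset_hi: int
    reference_kind: str  # median | minimum | most_recent | future_minimum
    trigger_kind: str  # ratio | absolute_rise
    ratio_threshold: float = RATIO_THRESHOLD
    rise_threshold: float = RISE_THRESHOLD


def standard_rules(criterion3_window_days: int = 2) -> dict[int, CriterionRule]:
    """The six criteria, with the 48-h window expressed as 1 or 2 days."""
    if criterion3_window_days not in (1, 2):
        raise ValueError("criterion3_window_days must be 1 or 2")
    return {
        1: CriterionRule(1, 8, 365, "median", "ratio"),
        2: CriterionRule(2, 1, 7, "minimum", "ratio"),
        3: CriterionRule(3, 1, criterion3_window_days, "minimum", "absolute_rise"),
        4: CriterionRule(4, -30, -1, "future_minimum", "ratio"),
        5: CriterionRule(5, 1, 1095, "most_recent", "ratio"),
        6: CriterionRule(6, 8, 365, "minimum", "ratio"),
    }


MODELS: dict[str, frozenset[int]] = {
    "A": frozenset({1, 2, 3}),
    "B": frozenset({1, 2, 3, 4}),
    "C": frozenset({1, 2, 3, 4, 5}),
    "D": frozenset({1, 2, 3, 4, 5, 6}),
}


@dataclass(frozen=True)
class DetectionModel:
    model_id: str
    criteria: frozenset[int]

    @classmethod
    def from_id(cls, model_id: str) -> "DetectionModel":
        try:
            return cls(model_id, MODELS[model_id.upper()])
        except KeyError:
            raise ValueError(f"unknown model {model_id!r}; expected A, B, C or D")


@dataclass(frozen=True)
class StagingRules:
    """KDIGO creatinine staging bands and the abnormal-flag bound."""

    stage1_rise: float = 26.0  # μmol/L, strict
    stage1_ratio: float = 1.5  # inclusive lower bound
    stage2_ratio: float = 2.0
    stage3_ratio: float = 3.0
    stage3_absolute: float = 354.0  # μmol/L index bound for adults
    paediatric_stage3_multiplier: float = 3.0  # × upper reference if age < 18
    adult_upper_reference: Mapping[str, float] = field(
        default_factory=lambda: {"female": 110.0, "male": 120.0}
    )


@dataclass(frozen=True)
class AkiAlert:
    patient_id: str
    day: int
    value: float
    criteria_met: frozenset[int]
    references: Mapping[int, float]  # per-criterion reference value, μmol/L
    ratio: float  # index / reference giving the highest stage among met criteria
    rise: float | None  # μmol/L over the 48-h reference, when available
    stage: int


@dataclass(frozen=True)
class NoBaselineFlag:
    patient_id: str
    day: int
    value: float
    reason: str = "abnormal value with no prior test within look-back"


@dataclass(frozen=True)
class AkiEpisode:
    patient_id: str
    first_alert_day: int
    alerts: tuple[AkiAlert, ...]
    n_alerts: int
    stage_at_first_detection: int
    peak_stage_within_30d: int
    location_at_first_alert: str  # inpatient | community
    days_since_previous_test_at_first_alert: int | None


def compute_reference(
    days: Sequence[int] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    index_day: int,
    rule: CriterionRule,
) -> float | None:
    """Reference creatinine for one criterion, or None when the window is empty.

    Median uses the mean-of-middle-two convention for even counts; the
    most-recent kind takes the value at the latest day in the window; the
    future-minimum looks at the window after the index.
    """
    vals = window_values(days, values, index_day, rule.offset_lo, rule.offset_hi)
    if len(vals) == 0:
        return None
    if rule.reference_kind == "median":
        return float(np.median(vals))
    if rule.reference_kind in ("minimum", "future_minimum"):
        return float(np.min(vals))
    if rule.reference_kind == "most_recent":
        return float(vals[-1])  # window_values preserves day order
    raise ValueError(f"unknown reference kind {rule.reference_kind!r}")


def _stage_for_reference(
    index_value: float,
    reference: float,
    rise_capable: bool,
    age: float,
    staging: StagingRules,
    upper_reference: float,
) -> int:
    ratio = index_value / reference
    stage3_bound = (
        staging.paediatric_stage3_multiplier * upper_reference
        if age < 18
        else staging.stage3_absolute
    )
    if ratio >= staging.stage3_ratio or (
        ratio >= staging.stage1_ratio and index_value > stage3_bound
    ):
        return 3
    if ratio >= staging.stage2_ratio:
        return 2
    if ratio >= staging.stage1_ratio:
        return 1
    if rise_capable and index_value - reference > staging.stage1_rise:
        return 1
    return 0


def stage_alert(
    index_value: float,
    references: Mapping[int, float],
    age: float,
    sex: str,
    staging: StagingRules = StagingRules(),
) -> int:
    """Stage of an alert: the maximum stage over the available references.

    ``references`` maps criterion id to reference value; the absolute-rise
    path (rise > 26 μmol/L implies at least Stage 1) applies only to the
    48-h reference (criterion 3). References not supporting any stage
    contribute nothing.
    """
    if not references:
        raise ValidationError("stage_alert requires at least one reference")
    upper = staging.adult_upper_reference[sex]
    return max(
        _stage_for_reference(index_value, ref, crit == 3, age, staging, upper)
        for crit, ref in references.items()
    )


def evaluate_test(
    days: np.ndarray,
    values: np.ndarray,
    index_pos: int,
    patient_id: str,
    model: DetectionModel,
    rules: Mapping[int, CriterionRule],
    staging: StagingRules,
    age: float,
    sex: str,
) -> AkiAlert | NoBaselineFlag | None:
    """Evaluate one index test of a patient's (deduplicated, sorted) series.

    Returns an alert if any criterion of the active model fires (ratio
    criteria trigger at >= 1.5 inclusive; the rise criterion at > 26 μmol/L
    strict); otherwise an abnormal-no-baseline flag if the value exceeds the
    sex-specific upper reference and no look-back reference exists at all
    (no prior test within 3 years, so the windows of criteria 1, 5 and 6
    are all empty and chronicity cannot be assessed); else None.
    """
    index_day = int(days[index_pos])
    index_value = float(values[index_pos])

    references: dict[int, float] = {}
    met: set[int] = set()
    for crit in sorted(model.criteria):
        try:
            rule = rules[crit]
        except KeyError:
            raise ValueError(f"model {model.model_id} requires a rule for criterion {crit}")
        ref = compute_reference(days, values, index_day, rule)
        if ref is None:
            continue
        references[crit] = ref
        if rule.trigger_kind == "ratio":
            if index_value / ref >= rule.ratio_threshold:
                met.add(crit)
        else:
            if index_value - ref > rule.rise_threshold:
                met.add(crit)

    if met:
        stage = stage_alert(index_value, references, age, sex, staging)
        best_ref = min(references.values())
        rise = index_value - references[3] if 3 in references else None
        return AkiAlert(
            patient_id=patient_id,
            day=index_day,
            value=index_value,
            criteria_met=frozenset(met),
            references=references,
            ratio=index_value / best_ref,
            rise=rise,
            stage=stage,
        )

    prior = window_values(days, values, index_day, 1, 1095)
    if len(prior) == 0 and index_value > staging.adult_upper_reference[sex]:
        return NoBaselineFlag(patient_id=patient_id, day=index_day, value=index_value)
    return None


def build_episode(
    patient_id: str,
    alerts: Sequence[AkiAlert],
    admissions: Sequence[tuple[int, int]],
    days: np.ndarray,
    study_window: tuple[int, int],
    horizon: int = 30,
) -> AkiEpisode | None:
    """Patient-level first episode: first in-window alert plus its peak stage.

    The peak stage is the highest stage among alerts within ``horizon`` days
    of first detection. Location is inpatient when the first alert day falls
    inside a half-open [admit, discharge) interval.
    """
    in_window = [a for a in alerts if study_window[0] <= a.day <= study_window[1]]
    if not in_window:
        return None
    in_window.sort(key=lambda a: a.day)
    first = in_window[0]
    peak = max(a.stage for a in in_window if a.day <= first.day + horizon)
    inpatient = any(admit <= first.day < discharge for admit, discharge in admissions)
    prior_days = days[days < first.day]
    days_since = int(first.day - prior_days[-1]) if len(prior_days) else None
    return AkiEpisode(
        patient_id=patient_id,
        first_alert_day=first.day,
        alerts=tuple(in_window),
        n_alerts=len(in_window),
        stage_at_first_detection=first.stage,
        peak_stage_within_30d=peak,
        location_at_first_alert="inpatient" if inpatient else "community",
        days_since_previous_test_at_first_alert=days_since,
    )


@dataclass(frozen=True)
class DetectorConfig:
    study_window: tuple[int, int]
    criterion3_window_days: int = 2
    staging: StagingRules = StagingRules()
    horizon_days: int = 30


def detect_cohort(
    tests: pd.DataFrame,
    patients: pd.DataFrame,
    model: DetectionModel | str,
    config: DetectorConfig,
) -> tuple[list[AkiEpisode], list[AkiAlert], list[NoBaselineFlag]]:
    """Run the detector over a cohort.

    Every index test inside the study window is evaluated against the
    patient's full multi-year series (tests outside the window supply
    references, including future tests for the retrospective criterion).
    ``tests`` must already be deduplicated; ``patients`` must carry sex, age
    and an ``admissions`` column of [admit, discharge) pairs.
    """
    if isinstance(model, str):
        model = DetectionModel.from_id(model)
    if patients["patient_id"].duplicated().any():
        dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"]
        raise ValidationError(f"duplicate patient ids: {sorted(set(dupes))[:10]}")
    rules = standard_rules(config.criterion3_window_days)
    lo, hi = config.study_window

    meta = patients.set_index("patient_id")
    episodes: list[AkiEpisode] = []
    alerts: list[AkiAlert] = []
    flags: list[NoBaselineFlag] = []

    for pid, group in tests.sort_values(["patient_id", "day"]).groupby(
        "patient_id", sort=True
    ):
        if pid not in meta.index:
            raise ValidationError(f"tests reference unknown patient {pid!r}")
        row = meta.loc[pid]
        days = group["day"].to_numpy(dtype=np.int64)
        values = group["value"].to_numpy(dtype=float)
        patient_alerts: list[AkiAlert] = []
        for pos in range(len(days)):
            if not (lo <= days[pos] <= hi):
                continue
            result = evaluate_test(
                days, values, pos, str(pid), model, rules, config.staging,
                float(row["age"]), str(row["sex"]),
            )
            if isinstance(result, AkiAlert):
                patient_alerts.append(result)
            elif isinstance(result, NoBaselineFlag):
                flags.append(result)
        if patient_alerts:
            alerts.extend(patient_alerts)
            episode = build_episode(
                str(pid), patient_alerts, row["admissions"], days,
                config.study_window, config.horizon_days,
            )
            if episode is not None:
                episodes.append(episode)

    logger.info(
        "model %s: %d alerts, %d episodes, %d no-baseline flags",
        model.model_id, len(alerts), len(episodes), len(flags),
    )
    return episodes, alerts, flags


def alerts_to_frame(alerts: Iterable[AkiAlert]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": a.patient_id,
            "day": a.day,
            "value": a.value,
            "criteria_met": ";".join(str(c) for c in sorted(a.criteria_met)),
            "ratio": a.ratio,
            "rise": a.rise,
            "stage": a.stage,
        }
        for a in alerts
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "day", "value", "criteria_met", "ratio", "rise", "stage"]
    )


def episodes_to_frame(episodes: Iterable[AkiEpisode]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": e.patient_id,
            "first_alert_day": e.first_alert_day,
            "n_alerts": e.n_alerts,
            "stage_at_first_detection": e.stage_at_first_detection,
            "peak_stage_within_30d": e.peak_stage_within_30d,
            "location_at_first_alert": e.location_at_first_alert,
            "days_since_previous_test": e.days_since_previous_test_at_first_alert,
        }
        for e in episodes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "first_alert_day", "n_alerts", "stage_at_first_detection",
            "peak_stage_within_30d", "location_at_first_alert", "days_since_previous_test",
        ],
    )


def flags_to_frame(flags: Iterable[NoBaselineFlag]) -> pd.DataFrame:
    rows = [
        {"patient_id": f.patient_id, "day": f.day, "value": f.value, "reason": f.reason}
        for f in flags
    ]
    return pd.DataFrame(rows, columns=["patient_id", "day", "value", "reason"])
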