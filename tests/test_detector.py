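import statistics

import numpy as np
import pandas as pd
import pytest

from akidetect import detector
from akidetect.detector import (
    AkiAlert,
    DetectionModel,
    DetectorConfig,
    NoBaselineFlag,
    StagingRules,
    build_episode,
    compute_reference,
    detect_cohort,
    evaluate_test,
    stage_alert,
    standard_rules,
)
from akidetect.timeline import ValidationError

from conftest import make_tests, make_patients

RULES = standard_rules()
STAGING = StagingRules()


def run_one(records, index_day, model="A", age=60.0, sex="male"):
    frame = make_tests(records)
    days = frame["day"].to_numpy()
    values = frame["value"].to_numpy(dtype=float)
    pos = int(np.where(days == index_day)[0][0])
    return evaluate_test(
        days, values, pos, "P1", DetectionModel.from_id(model), RULES, STAGING, age, sex
    )


class TestComputeReference:
    def test_median_of_lookback_window(self):
        frame = make_tests([(100, 80.0), (200, 100.0), (300, 120.0)])
        ref = compute_reference(frame["day"], frame["value"], 400, RULES[1])
        assert ref == 100.0

    def test_even_count_median_is_mean_of_middle_two(self):
        frame = make_tests([(100, 80.0), (150, 100.0), (200, 120.0), (300, 140.0)])
        ref = compute_reference(frame["day"], frame["value"], 400, RULES[1])
        assert ref == 110.0

    def test_most_recent_in_three_year_window(self):
        frame = make_tests([(0, 90.0), (370, 110.0)])
        ref = compute_reference(frame["day"], frame["value"], 400, RULES[5])
        assert ref == 110.0

    def test_empty_window_is_absent(self):
        frame = make_tests([(399, 80.0)])
        assert compute_reference(frame["day"], frame["value"], 400, RULES[1]) is None

    def test_future_minimum(self):
        frame = make_tests([(405, 95.0), (420, 70.0)])
        ref = compute_reference(frame["day"], frame["value"], 400, RULES[4])
        assert ref == 70.0


class TestEvaluateTest:
    def test_ratio_boundary_inclusive_triggers_criterion_1(self):
        alert = run_one(
            [(100, 80.0), (200, 100.0), (300, 120.0), (400, 150.0)], 400
        )
        assert isinstance(alert, AkiAlert)
        assert alert.criteria_met == frozenset({1})
        assert alert.stage == 1

    def test_rise_boundary_strict_for_criterion_3(self):
        alert = run_one([(399, 100.0), (400, 130.0)], 400)
        assert isinstance(alert, AkiAlert)
        assert 3 in alert.criteria_met
        assert alert.stage == 1
        assert run_one([(399, 100.0), (400, 126.0)], 400) is None

    def test_old_prior_only_reachable_by_model_c(self):
        records = [(0, 90.0), (400, 200.0)]
        assert run_one(records, 400, model="A") is None
        alert = run_one(records, 400, model="C")
        assert isinstance(alert, AkiAlert)
        assert alert.criteria_met == frozenset({5})
        assert alert.stage == 2  # ratio 2.22 falls in the [2, 3) band

    def test_abnormal_value_without_baseline_is_flagged(self):
        result = run_one([(400, 150.0)], 400, sex="female")
        assert isinstance(result, NoBaselineFlag)

    def test_normal_value_without_baseline_is_nothing(self):
        assert run_one([(400, 100.0)], 400, sex="male") is None

    def test_unknown_criterion_rule_is_configuration_error(self):
        frame = make_tests([(400, 150.0)])
        model = DetectionModel("X", frozenset({9}))
        with pytest.raises(ValueError, match="criterion 9"):
            evaluate_test(
                frame["day"].to_numpy(), frame["value"].to_numpy(dtype=float),
                0, "P1", model, RULES, STAGING, 60.0, "male",
            )


class TestStageAlert:
    def test_absolute_bound_promotes_to_stage_3(self):
        assert stage_alert(360.0, {1: 200.0}, 60, "male") == 3

    def test_maximum_over_references(self):
        assert stage_alert(250.0, {1: 120.0, 2: 80.0}, 60, "male") == 3

    def test_subthreshold_reference_contributes_nothing(self):
        # ratio 1.4 supports no stage; the other reference sets the stage
        assert stage_alert(140.0, {1: 100.0, 2: 80.0}, 60, "male") == 1

    def test_paediatric_absolute_bound_uses_reference_interval(self):
        # adult bound 354 not reached, but 3x upper reference (120) is
        assert stage_alert(365.0, {1: 200.0}, age=17, sex="male") == 3
        assert stage_alert(365.0, {1: 200.0}, age=17, sex="male", staging=STAGING) == 3
        assert stage_alert(350.0, {1: 200.0}, age=60, sex="male") == 1

    def test_empty_references_rejected(self):
        with pytest.raises(ValidationError):
            stage_alert(200.0, {}, 60, "male")


def _alert(day, stage):
    return AkiAlert("P1", day, 150.0, frozenset({1}), {1: 100.0}, 1.5, None, stage)


class TestBuildEpisode:
    def test_progression_to_stage_3_within_horizon(self):
        ep = build_episode(
            "P1", [_alert(10, 1), _alert(25, 3)], [], np.array([2, 10, 25]), (0, 365)
        )
        assert ep.stage_at_first_detection == 1
        assert ep.peak_stage_within_30d == 3
        assert ep.n_alerts == 2

    def test_single_alert_peak_equals_first_stage(self):
        ep = build_episode("P1", [_alert(10, 2)], [], np.array([10]), (0, 365))
        assert ep.peak_stage_within_30d == ep.stage_at_first_detection == 2

    def test_alert_beyond_horizon_does_not_raise_peak(self):
        ep = build_episode(
            "P1", [_alert(40, 1), _alert(75, 3)], [], np.array([40, 75]), (0, 365)
        )
        assert ep.peak_stage_within_30d == 1

    def test_location_and_recency(self):
        ep = build_episode(
            "P1", [_alert(10, 1)], [(8, 15)], np.array([3, 10]), (0, 365)
        )
        assert ep.location_at_first_alert == "inpatient"
        assert ep.days_since_previous_test_at_first_alert == 7
        ep2 = build_episode("P1", [_alert(10, 1)], [(20, 25)], np.array([10]), (0, 365))
        assert ep2.location_at_first_alert == "community"
        assert ep2.days_since_previous_test_at_first_alert is None

    def test_no_alert_in_study_window_gives_nothing(self):
        assert build_episode("P1", [_alert(400, 1)], [], np.array([400]), (0, 365)) is None


def brute_force_alerts(tests, patients, criteria, study_window):
    """Independent full-scan evaluation of every (index, window) pair."""
    spec = {
        1: (8, 365, "median", "ratio"),
        2: (1, 7, "min", "ratio"),
        3: (1, 2, "min", "rise"),
        4: (-30, -1, "min", "ratio"),
        5: (1, 1095, "recent", "ratio"),
        6: (8, 365, "min", "ratio"),
    }
    found = set()
    for pid, group in tests.groupby("patient_id"):
        recs = sorted(zip(group["day"], group["value"]))
        for d, v in recs:
            if not study_window[0] <= d <= study_window[1]:
                continue
            met = set()
            for c in criteria:
                off_lo, off_hi, kind, trig = spec[c]
                window = [(dd, vv) for dd, vv in recs if d - off_hi <= dd <= d - off_lo]
                if not window:
                    continue
                if kind == "median":
                    ref = statistics.median(vv for _, vv in window)
                elif kind == "min":
                    ref = min(vv for _, vv in window)
                else:
                    ref = max(window)[1]
                if trig == "ratio" and v / ref >= 1.5:
                    met.add(c)
                elif trig == "rise" and v - ref > 26:
                    met.add(c)
            if met:
                found.add((pid, d, frozenset(met)))
    return found


class TestDetectCohort:
    def test_empty_cohort(self, detector_config):
        episodes, alerts, flags = detect_cohort(
            make_tests([]), make_patients([]), "A", detector_config
        )
        assert episodes == [] and alerts == [] and flags == []

    def test_duplicate_patient_ids_rejected(self, detector_config):
        patients = pd.concat([make_patients(["P1"]), make_patients(["P1"])])
        with pytest.raises(ValidationError):
            detect_cohort(make_tests([(1, 80.0)]), patients, "A", detector_config)

    def test_matches_brute_force_on_small_random_cohorts(self):
        config = DetectorConfig(study_window=(500, 600))
        rng = np.random.default_rng(2003)
        for _ in range(40):
            n = int(rng.integers(1, 21))
            pids = rng.choice(["P1", "P2", "P3"], size=n)
            days = rng.integers(0, 650, size=n)
            values = np.round(rng.uniform(40, 400, size=n), 1)
            frame = make_tests(list(zip(pids, days, values)))
            frame = frame.drop_duplicates(["patient_id", "day"]).reset_index(drop=True)
            patients = make_patients(sorted(set(frame["patient_id"])))
            for model_id in ("A", "D"):
                _, alerts, _ = detect_cohort(frame, patients, model_id, config)
                got = {(a.patient_id, a.day, a.criteria_met) for a in alerts}
                expected = brute_force_alerts(
                    frame, patients, sorted(detector.MODELS[model_id]), (500, 600)
                )
                assert got == expected

    def test_deterministic_and_order_independent(self, cohort, detector_config):
        tests, patients, _ = cohort
        shuffled = tests.sample(frac=1, random_state=1).reset_index(drop=True)
        eps1, alerts1, flags1 = detect_cohort(tests, patients, "A", detector_config)
        eps2, alerts2, flags2 = detect_cohort(shuffled, patients, "A", detector_config)
        assert sorted((a.patient_id, a.day) for a in alerts1) == sorted(
            (a.patient_id, a.day) for a in alerts2
        )
        assert {e.patient_id for e in eps1} == {e.patient_id for e in eps2}

    def test_criterion_1_implies_criterion_6(self, cohort, detector_config):
        tests, patients, _ = cohort
        _, alerts, _ = detect_cohort(tests, patients, "D", detector_config)
        assert any(1 in a.criteria_met for a in alerts)
        for a in alerts:
            if 1 in a.criteria_met:
                assert 6 in a.criteria_met

    def test_every_alert_is_staged_and_justified(self, cohort, detector_config):
        tests, patients, _ = cohort
        _, alerts, _ = detect_cohort(tests, patients, "D", detector_config)
        for a in alerts:
            assert a.stage in (1, 2, 3)
            assert a.criteria_met
            assert a.ratio >= 1.5 or (a.rise is not None and a.rise > 26)
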