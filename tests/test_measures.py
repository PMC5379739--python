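"""Unit and property tests for the six adherence estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from adherekit.config import AnalysisConfig, DEFAULT_LANDMARKS
from adherekit.measures import (
    build_stock_ledger,
    compute_all,
    cpc_adherence,
    eamd_adherence,
    eamd_day_classification,
    pr_average_adherence,
    pr_gaps_adherence,
    select_landmark_vl,
    sr_adherence,
    tdm_features,
)

from conftest import (
    brute_force_medication_free_days,
    make_cohort,
    participant_row,
    window,
)

ANCHORS = ("efavirenz", "nevirapine", "lopinavir_r")


def disp_frame(entries, start="2020-01-01", drug="efavirenz"):
    start = pd.Timestamp(start)
    return pd.DataFrame({
        "participant_id": "P1",
        "dispense_date": [start + pd.Timedelta(days=d) for d, _ in entries],
        "drug": drug,
        "days_supplied": [s for _, s in entries],
    })


# ---------------------------------------------------------------------------
# Self-report


@pytest.mark.parametrize("answers,expected", [
    ((True, True, True), 100.0),
    ((False, False, False), 0.0),
    ((True, False, True), 66.7),
])
def test_sr_percent_of_three_days(answers, expected):
    assert round(sr_adherence(*answers), 1) == expected


def test_sr_requires_all_answers():
    with pytest.raises(ValueError):
        sr_adherence(True, float("nan"), True)


# ---------------------------------------------------------------------------
# Clinic pill count


@pytest.mark.parametrize("dispensed,returned,days,expected", [
    (30, 0, 30, 100.0),
    (60, 6, 60, 90.0),
    (30, 0, 28, 107.1),  # short interval: pill count exceeds 100%
])
def test_cpc_arithmetic(dispensed, returned, days, expected):
    start = pd.Timestamp("2020-01-01")
    value, flag = cpc_adherence(dispensed, returned, start,
                                start + pd.Timedelta(days=days), 1.0)
    assert round(value, 1) == expected
    assert flag == ""


def test_cpc_flags_returned_exceeding_dispensed():
    start = pd.Timestamp("2020-01-01")
    value, flag = cpc_adherence(30, 40, start, start + pd.Timedelta(days=30), 1.0)
    assert value is not None and value < 0
    assert flag == "returned_exceeds_dispensed"


def test_cpc_empty_interval_absent():
    start = pd.Timestamp("2020-01-01")
    value, flag = cpc_adherence(30, 0, start, start, 1.0)
    assert value is None


# ---------------------------------------------------------------------------
# Pharmacy refill, average method


@pytest.mark.parametrize("entries,period,expected", [
    ([(0, 28), (28, 28), (56, 28), (84, 28)], 112, 100.0),
    ([(0, 28), (23, 28), (51, 28), (79, 36)], 112, 107.1),  # early refills
    ([(0, 28), (28, 28), (56, 28)], 112, 75.0),
])
def test_pr_average_examples(entries, period, expected):
    value = pr_average_adherence(disp_frame(entries), window(period_days=period),
                                 ANCHORS)
    assert round(value, 1) == expected


def test_pr_average_ignores_non_anchor_drug():
    value = pr_average_adherence(disp_frame([(0, 112)], drug="other"),
                                 window(period_days=112), ANCHORS)
    assert value == 0.0


def test_pr_average_truncates_at_end_of_care():
    w = window(period_days=112)
    value = pr_average_adherence(
        disp_frame([(0, 56)]), w, ANCHORS,
        end_of_care_date=w.randomisation_date + pd.Timedelta(days=56))
    assert value == 100.0


# ---------------------------------------------------------------------------
# Stock ledger / PR-gaps


def test_ledger_exact_coverage_has_no_free_days():
    ledger = build_stock_ledger(disp_frame([(0, 28)]), window(period_days=28),
                                ANCHORS)
    assert ledger.medication_free_days == 0


def test_ledger_gap_between_refills():
    # 28-day supply at day 0, next refill day 35: days 28-34 uncovered
    ledger = build_stock_ledger(disp_frame([(0, 28), (35, 28)]),
                                window(period_days=56), ANCHORS)
    assert ledger.medication_free_days == 7


def test_ledger_early_refill_carries_surplus():
    ledger = build_stock_ledger(disp_frame([(0, 28), (23, 28)]),
                                window(period_days=56), ANCHORS)
    assert ledger.medication_free_days == 0
    assert ledger.stock[-1] == 0  # 56 supplied, 56 consumed

    ledger = build_stock_ledger(disp_frame([(0, 28), (23, 28), (51, 10)]),
                                window(period_days=56), ANCHORS)
    assert ledger.medication_free_days == 0
    assert ledger.stock[-1] == 10  # surplus carried past the period end


@pytest.mark.parametrize("free,period,expected", [
    (0, 112, 100.0), (112, 112, 0.0), (7, 140, 95.0),
])
def test_pr_gaps_percentage(free, period, expected):
    entries = [] if free == period else [(free, period - free)]
    ledger = build_stock_ledger(disp_frame(entries) if entries else
                                disp_frame([]).iloc[0:0],
                                window(period_days=period), ANCHORS)
    assert ledger.medication_free_days == free
    assert pr_gaps_adherence(ledger) == pytest.approx(expected)


@given(st.lists(st.tuples(st.integers(0, 199), st.integers(1, 60)),
                min_size=0, max_size=12),
       st.integers(1, 200))
def test_ledger_matches_brute_force_oracle(entries, period):
    entries = [(d, s) for d, s in entries if d < period]
    frame = disp_frame(entries) if entries else disp_frame([(0, 1)]).iloc[0:0]
    ledger = build_stock_ledger(frame, window(period_days=period), ANCHORS)
    free, surplus = brute_force_medication_free_days(entries, period)
    assert ledger.medication_free_days == free
    assert ledger.stock[-1] == surplus


@given(st.lists(st.tuples(st.integers(0, 111), st.integers(1, 56)),
                min_size=1, max_size=8),
       st.tuples(st.integers(0, 111), st.integers(1, 56)))
def test_refill_monotonicity(entries, extra):
    """Adding a dispensing never decreases PR-average or PR-gaps."""
    w = window(period_days=112)
    base = disp_frame(entries)
    more = disp_frame(entries + [extra])
    assert (pr_average_adherence(more, w, ANCHORS)
            >= pr_average_adherence(base, w, ANCHORS))
    assert (pr_gaps_adherence(build_stock_ledger(more, w, ANCHORS))
            >= pr_gaps_adherence(build_stock_ledger(base, w, ANCHORS)))


def test_pr_average_equals_pr_gaps_without_oversupply():
    # refills exactly when stock runs out, total supply <= period
    entries = [(0, 28), (28, 28), (56, 28), (84, 28)]
    w = window(period_days=112)
    frame = disp_frame(entries)
    avg = pr_average_adherence(frame, w, ANCHORS)
    gaps = pr_gaps_adherence(build_stock_ledger(frame, w, ANCHORS))
    assert avg == pytest.approx(gaps) == 100.0

    entries = [(0, 28), (35, 28), (70, 28)]  # gaps but no surplus at end
    w = window(period_days=98)
    frame = disp_frame(entries)
    assert pr_average_adherence(frame, w, ANCHORS) == pytest.approx(
        pr_gaps_adherence(build_stock_ledger(frame, w, ANCHORS)))


# ---------------------------------------------------------------------------
# EAMD


def events_frame(rows, start="2020-01-01"):
    start = pd.Timestamp(start)
    return pd.DataFrame({
        "participant_id": "P1",
        "timestamp": [start + pd.Timedelta(t) for t, _, _ in rows],
        "event_type": [e for _, e, _ in rows],
        "battery_voltage": [v for _, _, v in rows],
    })


def full_heartbeats(days, start="2020-01-01", voltage=3900):
    return [(pd.Timedelta(days=d, hours=12), "heartbeat", voltage)
            for d in range(days)]


def test_eamd_opening_within_day_window_is_adherent(config):
    rows = full_heartbeats(2) + [(pd.Timedelta(days=0, hours=20, minutes=15),
                                  "opening", 3900)]
    days = eamd_day_classification(events_frame(rows), window(period_days=2),
                                   config.battery_threshold)
    assert list(days["status"]) == ["adherent", "nonadherent"]


def test_eamd_early_morning_opening_credits_previous_day(config):
    # opening at 04:30 on day 1 falls in day 0's 06:00->05:59 window
    rows = full_heartbeats(2) + [(pd.Timedelta(days=1, hours=4, minutes=30),
                                  "opening", 3900)]
    days = eamd_day_classification(events_frame(rows), window(period_days=2),
                                   config.battery_threshold)
    assert list(days["status"]) == ["adherent", "nonadherent"]


def test_eamd_day_boundary_at_six_am(config):
    for offset, statuses in [
        (pd.Timedelta(days=1, hours=5, minutes=59, seconds=59),
         ["adherent", "nonadherent"]),
        (pd.Timedelta(days=1, hours=6), ["nonadherent", "adherent"]),
    ]:
        rows = full_heartbeats(2) + [(offset, "opening", 3900)]
        days = eamd_day_classification(events_frame(rows), window(period_days=2),
                                       config.battery_threshold)
        assert list(days["status"]) == statuses


def test_eamd_no_heartbeat_censors_day(config):
    rows = [(pd.Timedelta(days=0, hours=12), "heartbeat", 3900),
            (pd.Timedelta(days=1, hours=20), "opening", 3900)]
    days = eamd_day_classification(events_frame(rows), window(period_days=3),
                                   config.battery_threshold)
    # day 1 has an opening but no heartbeat; day 2 has nothing at all
    assert list(days["status"]) == ["nonadherent", "censored", "censored"]


def test_eamd_low_voltage_censors_day(config):
    rows = full_heartbeats(2)
    rows[1] = (rows[1][0], "heartbeat", config.battery_threshold - 1)
    rows.append((pd.Timedelta(days=1, hours=20), "opening", 3900))
    days = eamd_day_classification(events_frame(rows), window(period_days=2),
                                   config.battery_threshold)
    assert list(days["status"]) == ["nonadherent", "censored"]


def test_eamd_threshold_voltage_is_not_censored(config):
    rows = [(pd.Timedelta(days=0, hours=12), "heartbeat", config.battery_threshold)]
    days = eamd_day_classification(events_frame(rows), window(period_days=1),
                                   config.battery_threshold)
    assert list(days["status"]) == ["nonadherent"]


def test_eamd_translation_equivariance(config):
    """Shifting all events by +24h shifts day labels by exactly one day."""
    rng = np.random.default_rng(7)
    rows = []
    for d in range(10):
        if rng.random() < 0.8:
            rows.append((pd.Timedelta(days=d, hours=12), "heartbeat", 3900))
        if rng.random() < 0.6:
            rows.append((pd.Timedelta(days=d, hours=float(rng.uniform(6.1, 29.5))),
                         "opening", 3900))
    base = events_frame(rows)
    shifted = base.copy()
    shifted["timestamp"] = shifted["timestamp"] + pd.Timedelta(days=1)
    w = window(period_days=12)
    a = eamd_day_classification(base, w, config.battery_threshold)
    b = eamd_day_classification(shifted, w, config.battery_threshold)
    assert list(a["status"][:10]) == list(b["status"][1:11])


def test_eamd_adherence_denominator_excludes_censored():
    days = pd.DataFrame({
        "day": pd.date_range("2020-01-01", periods=120),
        "status": ["adherent"] * 100 + ["nonadherent"] * 12 + ["censored"] * 8,
    })
    value, detail = eamd_adherence(days)
    assert value == pytest.approx(100 * 100 / 112)
    assert round(value, 1) == 89.3
    assert detail["value_full_denominator"] == pytest.approx(100 * 100 / 120)
    assert detail["censored_days"] == 8


def test_eamd_all_censored_is_absent():
    days = pd.DataFrame({"day": pd.date_range("2020-01-01", periods=5),
                         "status": ["censored"] * 5})
    value, detail = eamd_adherence(days)
    assert value is None
    assert detail["censored_fraction"] == 1.0


def test_eamd_opening_monotonicity(config):
    """Adding an opening event never decreases EAMD adherence."""
    rows = full_heartbeats(30)
    rng = np.random.default_rng(11)
    for d in range(30):
        if rng.random() < 0.5:
            rows.append((pd.Timedelta(days=d, hours=20), "opening", 3900))
    w = window(period_days=30)
    base_value, _ = eamd_adherence(
        eamd_day_classification(events_frame(rows), w, config.battery_threshold))
    for d in (3, 17, 29):
        more = rows + [(pd.Timedelta(days=d, hours=21), "opening", 3900)]
        value, _ = eamd_adherence(eamd_day_classification(
            events_frame(more), w, config.battery_threshold))
        assert value >= base_value


# ---------------------------------------------------------------------------
# TDM


def test_tdm_features_examples():
    feats = tdm_features(2.3)
    assert round(feats["log10_value"], 4) == 0.3617
    assert feats["therapeutic_flag"]
    assert tdm_features(1.0)["log10_value"] == 0.0
    assert tdm_features(1.0)["therapeutic_flag"]
    assert not tdm_features(0.5)["therapeutic_flag"]
    assert not tdm_features(4.5)["therapeutic_flag"]


def test_tdm_floors_undetectable_before_log():
    feats = tdm_features(0.0, log_floor_mg_per_l=0.05)
    assert feats["log10_value"] == pytest.approx(np.log10(0.05))
    assert feats["raw_mg_per_l"] == 0.0


def test_tdm_negative_concentration_rejected():
    with pytest.raises(ValueError):
        tdm_features(-0.1)


# ---------------------------------------------------------------------------
# Landmark selection and the cohort driver


def labs_frame(day_values, start="2020-01-01"):
    start = pd.Timestamp(start)
    return pd.DataFrame({
        "participant_id": "P1",
        "sample_date": [start + pd.Timedelta(days=d) for d, _ in day_values],
        "hiv_rna_copies_per_ml": [v for _, v in day_values],
        "cd4": 300.0,
    })


def test_landmark_vl_closest_to_nominal_tie_earlier():
    spec = DEFAULT_LANDMARKS["week16"]
    start = pd.Timestamp("2020-01-01")
    w = select_landmark_vl(labs_frame([(100, 50.0), (120, 60.0)]), start, spec)
    assert w.vl_value == 60.0  # day 120 is 8 from nominal 112; day 100 is 12
    assert w.multiple_vls
    w = select_landmark_vl(labs_frame([(104, 50.0), (120, 60.0)]), start, spec)
    assert w.vl_value == 50.0  # tie at 8 days -> earlier wins


def test_landmark_vl_outside_window_excluded():
    spec = DEFAULT_LANDMARKS["week16"]
    start = pd.Timestamp("2020-01-01")
    assert select_landmark_vl(labs_frame([(150, 50.0)]), start, spec) is None


def _one_participant_cohort(labs_days, sr_day=None, pill=None):
    frames = {
        "participants": pd.DataFrame([participant_row()]),
        "labs": labs_frame(labs_days),
    }
    start = pd.Timestamp("2020-01-01")
    if sr_day is not None:
        frames["self_report"] = pd.DataFrame([{
            "participant_id": "P1",
            "visit_date": start + pd.Timedelta(days=sr_day),
            "took_day1": True, "took_day2": True, "took_day3": True}])
    if pill is not None:
        disp_day, count_day = pill
        frames["pill_returns"] = pd.DataFrame([{
            "participant_id": "P1",
            "count_date": start + pd.Timedelta(days=count_day),
            "drug": "efavirenz",
            "tablets_dispensed_since_last": 28, "tablets_returned": 0,
            "last_dispense_date": start + pd.Timedelta(days=disp_day),
            "doses_per_day": 1.0}])
    return make_cohort(**frames)


def test_compute_all_window_logic(config):
    cohort = _one_participant_cohort([(100, 50.0)])
    assert set(compute_all(cohort, "week16", config)["method"]) == set()
    # no dispensing/EAMD/SR streams -> no estimates, but participant included
    cohort = _one_participant_cohort([(100, 50.0)], sr_day=100)
    est = compute_all(cohort, "week16", config)
    assert set(est["method"]) == {"SR"}

    cohort = _one_participant_cohort([(150, 50.0)], sr_day=150)
    assert compute_all(cohort, "week16", config).empty  # day 150 outside 84-140
    assert compute_all(cohort, "week48", config).empty  # and outside 224-448


def test_compute_all_missed_study_visit_keeps_cpc(config):
    # pill data from the clinic folder, but no study visit: CPC present,
    # SR and TDM absent
    cohort = _one_participant_cohort([(112, 50.0)], pill=(84, 112))
    est = compute_all(cohort, "week16", config)
    assert set(est["method"]) == {"CPC"}
    cpc = est[est["method"] == "CPC"].iloc[0]
    assert cpc["value"] == 100.0
    assert cpc["denominator_days"] == 28
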