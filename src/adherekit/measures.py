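"""The six adherence estimators and the per-protocol landmark machinery.

Each estimator maps raw streams to an adherence value for one participant at
one landmark (week 16 or week 48):

* **SR** — 3-day self-recall: percent of the last three days reported dosed.
* **CPC** — clinic pill count: (tablets dispensed − returned) / expected doses
  over the interval since the last dispensing; may exceed 100%.
* **PR-average** — days of anchor-drug supply dispensed divided by days in
  care; early refills push it above 100%.
* **PR-gaps** — 100 × (period − medication-free days) / period, where a
  medication-free day is one on which the participant could not have had
  drug in hand given dispensing dates and quantities; bounded in [0, 100].
* **EAMD** — adherent monitor days / non-censored days in care, where a day
  runs 06:00→05:59 local and dead-battery days are censored.
* **TDM** — mid-dose efavirenz concentration (mg/L); models consume log10.

All day arithmetic is half-open ``[start, end)``; the cumulative adherence
period is ``[randomisation, vl_date)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, LandmarkSpec
from .io import Cohort

DAY_START_HOUR = 6  # monitor days are anchored at 06:00 local time

ADHERENT = "adherent"
NONADHERENT = "nonadherent"
CENSORED = "censored"

ESTIMATE_COLUMNS = (
    "participant_id", "method", "landmark", "value", "window_start",
    "window_end", "denominator_days", "flag",
)


@dataclass(frozen=True)
class LandmarkWindow:
    """A participant's realised landmark: the chosen viral-load date and the
    cumulative adherence period ``[randomisation, vl_date)``."""

    landmark: str
    randomisation_date: pd.Timestamp
    vl_date: pd.Timestamp
    vl_value: float
    multiple_vls: bool = False

    @property
    def period_days(self) -> int:
        return (self.vl_date - self.randomisation_date).days

    def day_index(self, date: pd.Timestamp) -> int:
        return (date - self.randomisation_date).days


def select_landmark_vl(
    labs: pd.DataFrame,
    randomisation_date: pd.Timestamp,
    spec: LandmarkSpec,
) -> LandmarkWindow | None:
    """Pick the qualifying HIV-RNA for one participant at one landmark.

    A result qualifies if its day offset from randomisation lies inside the
    landmark window (inclusive).  With several qualifying results the one
    closest to the nominal landmark day is used, earlier date breaking ties;
    the estimate is flagged so the choice is visible downstream.
    """
    if labs.empty:
        return None
    offsets = _day_offsets(labs["sample_date"], randomisation_date)
    in_window = (offsets >= spec.window_start_day) & (offsets <= spec.window_end_day)
    if not in_window.any():
        return None
    cand_off = offsets[in_window]
    dist = np.abs(cand_off - spec.nominal_day)
    pick = np.lexsort((cand_off, dist))[0]
    chosen = labs.iloc[np.flatnonzero(in_window)[pick]]
    return LandmarkWindow(
        landmark=spec.name,
        randomisation_date=randomisation_date,
        vl_date=chosen["sample_date"],
        vl_value=float(chosen["hiv_rna_copies_per_ml"]),
        multiple_vls=int(in_window.sum()) > 1,
    )


def _day_offsets(dates: pd.Series, origin: pd.Timestamp) -> np.ndarray:
    """Whole-day offsets of a date column from an origin (numpy fast path)."""
    arr = dates.to_numpy().astype("datetime64[D]")
    return (arr - np.datetime64(origin, "D")).astype(np.int64)


# ---------------------------------------------------------------------------
# Self-report


def sr_adherence(took_day1: bool, took_day2: bool, took_day3: bool) -> float:
    """Percent of the last three days dosed, from the 3-day recall answers."""
    answers = (took_day1, took_day2, took_day3)
    if any(a is None or (isinstance(a, float) and math.isnan(a)) for a in answers):
        raise ValueError("all three recall answers are required")
    return 100.0 * sum(bool(a) for a in answers) / 3.0


# ---------------------------------------------------------------------------
# Clinic pill count


def cpc_adherence(
    tablets_dispensed_since_last: float,
    tablets_returned: float,
    last_dispense_date: pd.Timestamp,
    count_date: pd.Timestamp,
    doses_per_day: float,
) -> tuple[float | None, str]:
    """Pill-count adherence over the interval since the last dispensing.

    Returns ``(value, flag)``; value is None when the interval is empty.  A
    return count exceeding the dispensed count implies undisclosed stock: the
    estimate is still computed but flagged.
    """
    days_between = (count_date - last_dispense_date).days
    if days_between <= 0 or doses_per_day <= 0:
        return None, "empty_interval"
    taken = tablets_dispensed_since_last - tablets_returned
    value = 100.0 * taken / (days_between * doses_per_day)
    flag = "returned_exceeds_dispensed" if tablets_returned > tablets_dispensed_since_last else ""
    return value, flag


# ---------------------------------------------------------------------------
# Pharmacy refill


def _anchor_dispensings(
    dispensings: pd.DataFrame, window: LandmarkWindow, anchor_drugs: Sequence[str]
) -> pd.DataFrame:
    if dispensings.empty:
        return dispensings
    dates = dispensings["dispense_date"].to_numpy()
    mask = (
        np.isin(dispensings["drug"].to_numpy(), anchor_drugs)
        & (dates >= np.datetime64(window.randomisation_date))
        & (dates < np.datetime64(window.vl_date))
    )
    return dispensings[mask]


def pr_average_adherence(
    dispensings: pd.DataFrame,
    window: LandmarkWindow,
    anchor_drugs: Sequence[str],
    end_of_care_date: pd.Timestamp | None = None,
) -> float | None:
    """Days of anchor-drug supply received over days in care, as a percent.

    Days in care run from randomisation to the landmark viral-load date,
    truncated at the end-of-care date if that came first.  Early refills can
    push the value above 100%.
    """
    end = window.vl_date
    if end_of_care_date is not None and not pd.isna(end_of_care_date):
        end = min(end, end_of_care_date)
    days_in_care = (end - window.randomisation_date).days
    if days_in_care <= 0:
        return None
    supplied = _anchor_dispensings(dispensings, window, anchor_drugs)["days_supplied"].sum()
    return 100.0 * float(supplied) / days_in_care


@dataclass
class StockLedger:
    """Daily anchor-drug stock over the adherence period.

    ``stock[d]`` is the days of supply on hand at the end of day ``d`` (after
    that day's consumption); surplus from early refills carries forward
    without cap.  A medication-free day is one where no dose could be
    consumed because stock was exhausted.
    """

    participant_id: str
    start: pd.Timestamp
    stock: np.ndarray
    medication_free_days: int

    @property
    def period_days(self) -> int:
        return len(self.stock)


def build_stock_ledger(
    dispensings: pd.DataFrame,
    window: LandmarkWindow,
    anchor_drugs: Sequence[str],
    participant_id: str = "",
) -> StockLedger:
    """Simulate daily stock on hand over ``[randomisation, vl_date)``.

    On each day, supply dispensed that day is added first, then one day of
    supply is consumed if any is on hand; otherwise the day counts as
    medication-free.
    """
    n_days = window.period_days
    anchored = _anchor_dispensings(dispensings, window, anchor_drugs)
    additions = np.zeros(n_days, dtype=np.int64)
    if len(anchored):
        offsets = _day_offsets(anchored["dispense_date"], window.randomisation_date)
        np.add.at(additions, offsets, anchored["days_supplied"].to_numpy())
    stock = np.zeros(n_days, dtype=np.int64)
    on_hand = 0
    free = 0
    for d in range(n_days):
        on_hand += additions[d]
        if on_hand > 0:
            on_hand -= 1
        else:
            free += 1
        stock[d] = on_hand
    return StockLedger(participant_id=participant_id, start=window.randomisation_date,
                       stock=stock, medication_free_days=free)


def pr_gaps_adherence(ledger: StockLedger) -> float | None:
    """Percent of period days that were not medication-free; in [0, 100]."""
    if ledger.period_days == 0:
        return None
    return 100.0 * (ledger.period_days - ledger.medication_free_days) / ledger.period_days


# ---------------------------------------------------------------------------
# Electronic adherence monitoring


def eamd_monitor_day(timestamps: pd.Series | pd.DatetimeIndex) -> pd.Series:
    """Map event timestamps to monitor days (a day runs 06:00 → 05:59+1)."""
    ts = pd.to_datetime(pd.Series(timestamps))
    return (ts - pd.Timedelta(hours=DAY_START_HOUR)).dt.normalize()


def eamd_day_classification(
    events: pd.DataFrame,
    window: LandmarkWindow,
    battery_threshold: int,
) -> pd.DataFrame:
    """Classify every day of the adherence period as adherent / nonadherent /
    censored.

    A day is censored when it has no heartbeat event in its 06:00→05:59
    interval, or when the minimum battery reading among its events falls
    below ``battery_threshold`` (dead-battery day).  Otherwise it is adherent
    iff at least one opening event falls in the interval.  An opening at
    exactly 05:59:59 credits the previous day; at 06:00:00 the current day.
    """
    n_days = window.period_days
    days = pd.date_range(window.randomisation_date, periods=n_days, freq="D")
    opened = np.zeros(n_days, dtype=bool)
    heartbeat = np.zeros(n_days, dtype=bool)
    min_voltage = np.full(n_days, np.inf)

    if len(events):
        ts = events["timestamp"].to_numpy()
        mday = (ts - np.timedelta64(DAY_START_HOUR, "h")).astype("datetime64[D]")
        offsets = (mday - np.datetime64(window.randomisation_date, "D")).astype(np.int64)
        in_period = (offsets >= 0) & (offsets < n_days)
        offs = offsets[in_period]
        etype = events["event_type"].to_numpy()[in_period]
        voltage = events["battery_voltage"].to_numpy(dtype=float)[in_period]
        opened[offs[etype == "opening"]] = True
        heartbeat[offs[etype == "heartbeat"]] = True
        np.minimum.at(min_voltage, offs, voltage)

    censored = (~heartbeat) | (min_voltage < battery_threshold)
    status = np.where(censored, CENSORED, np.where(opened, ADHERENT, NONADHERENT))
    return pd.DataFrame({"day": days, "status": status})


def eamd_adherence(day_status: pd.DataFrame) -> tuple[float | None, dict]:
    """Adherent days over non-censored days in care, as a percent.

    Censored (dead-battery) days are removed from the denominator so that a
    dead device does not masquerade as non-adherence.  The full-denominator
    variant and the censored-day fraction are reported alongside in the
    detail dict so the alternative convention is recoverable.
    """
    total = len(day_status)
    counts = day_status["status"].value_counts()
    adherent = int(counts.get(ADHERENT, 0))
    censored = int(counts.get(CENSORED, 0))
    detail = {
        "days_in_care": total,
        "adherent_days": adherent,
        "censored_days": censored,
        "censored_fraction": (censored / total) if total else float("nan"),
        "value_full_denominator": (100.0 * adherent / total) if total else None,
    }
    denominator = total - censored
    if denominator <= 0:
        return None, detail
    return 100.0 * adherent / denominator, detail


# ---------------------------------------------------------------------------
# Therapeutic drug monitoring


def tdm_features(
    efv_mg_per_l: float, log_floor_mg_per_l: float = 0.05
) -> dict[str, float | bool]:
    """Raw concentration, log10 model input and therapeutic-range flag.

    The therapeutic range for mid-dose efavirenz is 1–4 mg/L (inclusive).
    Undetectable (zero) concentrations are floored before the log transform.
    """
    if efv_mg_per_l < 0:
        raise ValueError("efavirenz concentration must be non-negative")
    floored = max(efv_mg_per_l, log_floor_mg_per_l)
    return {
        "raw_mg_per_l": float(efv_mg_per_l),
        "log10_value": math.log10(floored),
        "therapeutic_flag": 1.0 <= efv_mg_per_l <= 4.0,
    }


# ---------------------------------------------------------------------------
# Cohort-level driver


def _closest_visit_row(
    frame: pd.DataFrame, date_col: str, window: LandmarkWindow, spec: LandmarkSpec
) -> pd.Series | None:
    """Row whose visit date falls in the landmark window, closest to the
    realised viral-load date (tie -> earlier)."""
    if frame.empty:
        return None
    offsets = _day_offsets(frame[date_col], window.randomisation_date)
    in_window = (offsets >= spec.window_start_day) & (offsets <= spec.window_end_day)
    if not in_window.any():
        return None
    vl_off = window.period_days
    cand_off = offsets[in_window]
    dist = np.abs(cand_off - vl_off)
    pick = np.lexsort((cand_off, dist))[0]
    return frame.iloc[np.flatnonzero(in_window)[pick]]


def participant_landmark(
    cohort: Cohort, participant_id: str, landmark: str,
    config: AnalysisConfig,
) -> LandmarkWindow | None:
    """Resolve one participant's landmark window (None if per-protocol
    excluded: no qualifying viral load)."""
    spec = config.landmark(landmark)
    prow = cohort.participants[cohort.participants["participant_id"] == participant_id]
    if prow.empty:
        return None
    rand_date = prow.iloc[0]["randomisation_date"]
    labs = cohort.for_participant("labs", participant_id)
    return select_landmark_vl(labs, rand_date, spec)


def compute_all(
    cohort: Cohort,
    landmark: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """All six adherence estimates for every per-protocol participant.

    Participants without a qualifying HIV-RNA in the landmark window are
    excluded (per-protocol, no imputation).  Missing streams yield absent
    estimates for the affected method only; rows are tidy
    (participant, method, landmark, value, window, denominator, flag).
    """
    config = config or AnalysisConfig()
    spec = config.landmark(landmark)
    rows: list[dict] = []

    def _by_participant(stream: str) -> dict:
        frame = cohort.stream(stream)
        return dict(tuple(frame.groupby("participant_id", sort=False))) if len(frame) else {}

    empty = {name: cohort.stream(name).iloc[0:0] for name in
             ("labs", "self_report", "pill_returns", "dispensing",
              "eamd_events", "efv_concentrations")}
    grouped = {name: _by_participant(name) for name in empty}

    participants = cohort.participants.set_index("participant_id", drop=False)
    for pid, prow in participants.iterrows():
        window = select_landmark_vl(
            grouped["labs"].get(pid, empty["labs"]), prow["randomisation_date"], spec)
        if window is None:
            continue
        base = {
            "participant_id": pid,
            "landmark": landmark,
            "window_start": window.randomisation_date,
            "window_end": window.vl_date,
            "denominator_days": window.period_days,
            "flag": "multiple_vls" if window.multiple_vls else "",
        }

        sr = _closest_visit_row(
            grouped["self_report"].get(pid, empty["self_report"]), "visit_date", window, spec)
        if sr is not None:
            rows.append({**base, "method": "SR",
                         "value": sr_adherence(sr["took_day1"], sr["took_day2"], sr["took_day3"]),
                         "window_start": sr["visit_date"] - pd.Timedelta(days=3),
                         "window_end": sr["visit_date"], "denominator_days": 3})

        pill = _closest_visit_row(
            grouped["pill_returns"].get(pid, empty["pill_returns"]), "count_date", window, spec)
        if pill is not None and pill["drug"] in config.anchor_drugs:
            value, flag = cpc_adherence(
                pill["tablets_dispensed_since_last"], pill["tablets_returned"],
                pill["last_dispense_date"], pill["count_date"], pill["doses_per_day"])
            if value is not None:
                rows.append({**base, "method": "CPC", "value": value,
                             "window_start": pill["last_dispense_date"],
                             "window_end": pill["count_date"],
                             "denominator_days": (pill["count_date"] - pill["last_dispense_date"]).days,
                             "flag": ";".join(f for f in (base["flag"], flag) if f)})

        dispensings = grouped["dispensing"].get(pid, empty["dispensing"])
        pr_avg = pr_average_adherence(
            dispensings, window, config.anchor_drugs,
            end_of_care_date=prow.get("end_of_care_date"))
        if pr_avg is not None and len(
                _anchor_dispensings(dispensings, window, config.anchor_drugs)):
            rows.append({**base, "method": "PR_AVERAGE", "value": pr_avg})

            ledger = build_stock_ledger(dispensings, window, config.anchor_drugs, pid)
            pr_gap = pr_gaps_adherence(ledger)
            if pr_gap is not None:
                rows.append({**base, "method": "PR_GAPS", "value": pr_gap})

        events = grouped["eamd_events"].get(pid, empty["eamd_events"])
        if len(events):
            day_status = eamd_day_classification(events, window, config.battery_threshold)
            value, detail = eamd_adherence(day_status)
            flag = base["flag"]
            if value is None:
                flag = ";".join(f for f in (flag, "all_days_censored") if f)
            else:
                rows.append({**base, "method": "EAMD", "value": value,
                             "flag": flag,
                             "censored_days": detail["censored_days"],
                             "value_full_denominator": detail["value_full_denominator"]})

        tdm = _closest_visit_row(
            grouped["efv_concentrations"].get(pid, empty["efv_concentrations"]), "sample_date", window, spec)
        if tdm is not None:
            feats = tdm_features(tdm["efv_mg_per_l"], config.efv_log_floor_mg_per_l)
            rows.append({**base, "method": "TDM", "value": feats["raw_mg_per_l"],
                         "window_start": tdm["sample_date"],
                         "window_end": tdm["sample_date"], "denominator_days": 0,
                         "therapeutic_flag": feats["therapeutic_flag"]})

    if not rows:
        return pd.DataFrame(columns=list(ESTIMATE_COLUMNS))
    out = pd.DataFrame(rows)
    ordered = [c for c in ESTIMATE_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in ordered]
    return out[ordered + extra]
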