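import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from adherekit.config import AnalysisConfig
from adherekit.io import SCHEMAS, Cohort
from adherekit.measures import LandmarkWindow
from adherekit.simulate import generate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def sim():
    """One default synthetic cohort shared by read-only tests."""
    return generate(seed=123)


def empty_stream(name: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=list(SCHEMAS[name]))
    for col in df.columns:
        if "date" in col or col == "timestamp":
            df[col] = pd.to_datetime(df[col])
    return df


def make_cohort(**frames) -> Cohort:
    """Cohort with explicit frames; unspecified streams are empty."""
    full = {name: frames.get(name, empty_stream(name)) for name in SCHEMAS}
    for name, frame in full.items():
        for col in frame.columns:
            if ("date" in col or col == "timestamp") and frame[col].dtype == object:
                frame[col] = pd.to_datetime(frame[col])
    return Cohort(**full)


def window(start="2020-01-01", period_days=112, landmark="week48",
           vl_value=0.0) -> LandmarkWindow:
    start = pd.Timestamp(start)
    return LandmarkWindow(landmark=landmark, randomisation_date=start,
                          vl_date=start + pd.Timedelta(days=period_days),
                          vl_value=vl_value)


def participant_row(pid="P1", rand_date="2020-01-01", **over) -> dict:
    row = {
        "participant_id": pid, "sex": "female", "age_years": 34.0,
        "baseline_cd4": 225.0, "baseline_log10_vl": 4.9,
        "randomisation_date": pd.Timestamp(rand_date),
        "end_of_care_date": pd.NaT, "care_status": "in_care",
    }
    row.update(over)
    return row


def brute_force_medication_free_days(dispensings: list[tuple[int, int]],
                                     period_days: int) -> tuple[int, int]:
    """Independent day-by-day possession oracle.

    ``dispensings`` is a list of (day offset, days supplied).  Walks every
    day with explicit pill-by-pill bookkeeping; returns (medication-free
    days, pills on hand at the period end).
    """
    pills = 0
    free = 0
    supply_by_day: dict[int, int] = {}
    for day, amount in dispensings:
        supply_by_day[day] = supply_by_day.get(day, 0) + amount
    for day in range(period_days):
        pills += supply_by_day.get(day, 0)
        if pills == 0:
            free += 1
        else:
            pills -= 1
    return free, pills


def brute_force_auc(scores, y) -> float:
    """All-pairs concordance oracle for the AUC (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
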