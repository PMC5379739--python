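"""Descriptive tabulations of a cohort: the counting operations.

These are the pipeline's counting operations: per-method median (IQR)
adherence, viral-suppression proportions, dead-battery day fractions,
mutation prevalence among amplified genotypes, and retention-in-care
summaries.  Percentages are rounded to one decimal place at presentation;
underlying values keep full precision.
"""

from __future__ import annotations

import pandas as pd

from .io import METHODS
from .measures import CENSORED


def adherence_summary(estimates: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) and n per method and landmark (the Table-2 shape)."""
    rows = []
    for (landmark, method), group in estimates.groupby(["landmark", "method"]):
        values = group["value"].astype(float)
        rows.append({
            "landmark": landmark,
            "method": method,
            "n": len(values),
            "median": float(values.median()),
            "q1": float(values.quantile(0.25)),
            "q3": float(values.quantile(0.75)),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    order = {m: i for i, m in enumerate(METHODS)}
    out["_ord"] = out["method"].map(order)
    return out.sort_values(["landmark", "_ord"]).drop(columns="_ord").reset_index(drop=True)


def suppression_proportion(outcomes: pd.DataFrame) -> dict:
    """Viral suppression at the landmark: n, suppressed count, percent.

    Suppression is the complement of virological failure at that landmark's
    threshold (<=400 copies/ml at week 16, <=40 at week 48).
    """
    n = len(outcomes)
    suppressed = int((~outcomes["failed"].astype(bool)).sum())
    return {
        "n": n,
        "suppressed": suppressed,
        "percent": round(100.0 * suppressed / n, 1) if n else float("nan"),
    }


def dead_battery_fraction(day_status: pd.DataFrame) -> dict:
    """Censored (dead-battery) monitor days over all recorded days."""
    total = len(day_status)
    censored = int((day_status["status"] == CENSORED).sum())
    return {
        "total_days": total,
        "censored_days": censored,
        "percent": round(100.0 * censored / total, 1) if total else float("nan"),
    }


def mutation_prevalence(genotypes: pd.DataFrame, mutation: str) -> dict:
    """Prevalence of one mutation among successfully amplified genotypes."""
    amplified = genotypes[genotypes["amplified"].astype(bool)]
    n = len(amplified)
    carriers = int(amplified["mutations"].apply(lambda ms: mutation in ms).sum())
    return {
        "n_amplified": n,
        "carriers": carriers,
        "percent": round(100.0 * carriers / n, 1) if n else float("nan"),
    }


def care_status_summary(participants: pd.DataFrame) -> pd.DataFrame:
    """Retention in care: count and percent per care status."""
    n = len(participants)
    counts = participants["care_status"].value_counts()
    rows = [{
        "care_status": status,
        "count": int(count),
        "percent": round(100.0 * count / n, 1),
    } for status, count in counts.items()]
    return pd.DataFrame(rows)


def availability_counts(estimates: pd.DataFrame) -> pd.DataFrame:
    """Participants contributing each measure at each landmark."""
    return (estimates.groupby(["landmark", "method"])["participant_id"]
            .nunique().rename("n").reset_index())


def therapeutic_fraction(estimates: pd.DataFrame, landmark: str,
                         lower: float = 1.0) -> dict:
    """Fraction of TDM samples at or above the therapeutic lower bound."""
    tdm = estimates[(estimates["method"] == "TDM")
                    & (estimates["landmark"] == landmark)]
    n = len(tdm)
    above = int((tdm["value"].astype(float) > lower).sum())
    return {"n": n, "above": above,
            "percent": round(100.0 * above / n, 1) if n else float("nan")}
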