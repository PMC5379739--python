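"""Delimited-text readers/writers and cohort validation.

The input contract is a directory of UTF-8 CSVs with fixed column names
(documented per stream below).  ``read_cohort`` loads and validates every
stream into a :class:`Cohort` of pandas DataFrames, sorting per-participant
streams by date (stable, tie-break on input row order) and removing obvious
dispensing duplicates (same participant, date, drug and quantity).  Row-level
problems are collected as :class:`RowIssue` records rather than raised, except
for structural defects (missing columns, duplicate participant ids) which
abort the load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import AnalysisConfig

log = logging.getLogger(__name__)

METHODS = ("SR", "CPC", "PR_AVERAGE", "PR_GAPS", "EAMD", "TDM")

SEX_VALUES = {"female", "male"}
CARE_STATUS_VALUES = {"in_care", "transferred", "died", "ltfu", "withdrew"}
DRUG_VALUES = {"efavirenz", "nevirapine", "lopinavir_r", "other"}
EAMD_EVENT_TYPES = {"opening", "heartbeat"}

#: filename -> required columns for each input stream
SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "participants": (
        "participant_id", "sex", "age_years", "baseline_cd4",
        "baseline_log10_vl", "randomisation_date", "end_of_care_date",
        "care_status",
    ),
    "dispensing": ("participant_id", "dispense_date", "drug", "days_supplied"),
    "eamd_events": ("participant_id", "timestamp", "event_type", "battery_voltage"),
    "pill_returns": (
        "participant_id", "count_date", "drug", "tablets_dispensed_since_last",
        "tablets_returned", "last_dispense_date", "doses_per_day",
    ),
    "self_report": ("participant_id", "visit_date", "took_day1", "took_day2", "took_day3"),
    "efv_concentrations": (
        "participant_id", "sample_date", "efv_mg_per_l", "reported_last_dose_time",
    ),
    "labs": ("participant_id", "sample_date", "hiv_rna_copies_per_ml", "cd4"),
    "genotypes": ("participant_id", "sample_date", "mutations", "amplified"),
}

_DATE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "participants": ("randomisation_date", "end_of_care_date"),
    "dispensing": ("dispense_date",),
    "eamd_events": ("timestamp",),
    "pill_returns": ("count_date", "last_dispense_date"),
    "self_report": ("visit_date",),
    "efv_concentrations": ("sample_date",),
    "labs": ("sample_date",),
    "genotypes": ("sample_date",),
}

_SORT_KEYS: Mapping[str, str] = {
    "dispensing": "dispense_date",
    "eamd_events": "timestamp",
    "pill_returns": "count_date",
    "self_report": "visit_date",
    "efv_concentrations": "sample_date",
    "labs": "sample_date",
    "genotypes": "sample_date",
}


class SchemaError(ValueError):
    """An input file is structurally unusable (missing column, bad header)."""


@dataclass(frozen=True)
class RowIssue:
    stream: str
    line: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"{self.stream}" + (f":{self.line}" if self.line is not None else "")
        return f"[{where}] {self.message}"


@dataclass
class Cohort:
    """Validated in-memory bundle of all input streams.

    Every frame is sorted per participant by its natural date column; the
    dispensing frame is de-duplicated.  ``issues`` lists rejected rows and
    removed duplicates.
    """

    participants: pd.DataFrame
    dispensing: pd.DataFrame
    eamd_events: pd.DataFrame
    pill_returns: pd.DataFrame
    self_report: pd.DataFrame
    efv_concentrations: pd.DataFrame
    labs: pd.DataFrame
    genotypes: pd.DataFrame
    issues: list[RowIssue] = field(default_factory=list)

    def stream(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants["participant_id"])

    def for_participant(self, stream: str, participant_id: str) -> pd.DataFrame:
        frame = self.stream(stream)
        return frame[frame["participant_id"] == participant_id]


def _require_columns(df: pd.DataFrame, stream: str) -> None:
    missing = [c for c in SCHEMAS[stream] if c not in df.columns]
    if missing:
        raise SchemaError(f"{stream}: missing required column(s) {missing}")


def _parse_dates(
    df: pd.DataFrame, stream: str, issues: list[RowIssue], required: Iterable[str]
) -> pd.DataFrame:
    """Parse date columns; rows with unparseable *required* dates are dropped."""
    required = set(required)
    for col in _DATE_COLUMNS.get(stream, ()):
        raw = df[col]
        parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        for idx in df.index[bad]:
            # +2: header line plus 1-based numbering
            issues.append(RowIssue(stream, int(idx) + 2, f"unparseable date in {col!r}: {raw[idx]!r}"))
        df[col] = parsed
        if col in required:
            df = df[df[col].notna()]
    return df.copy()  # keep original index (line numbers) but own the data


def _reject(df: pd.DataFrame, mask: pd.Series, stream: str, message: str,
            issues: list[RowIssue]) -> pd.DataFrame:
    mask = mask.fillna(False) if mask.dtype == object else mask
    for idx in df.index[mask]:
        issues.append(RowIssue(stream, int(idx) + 2, message))
    return df[~mask].copy()


def _parse_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    return series.astype(str).str.strip().str.lower().map(mapping)


def dedupe_dispensing(df: pd.DataFrame, issues: list[RowIssue] | None = None) -> pd.DataFrame:
    """Drop obvious dispensing duplicates, keeping the first occurrence.

    A duplicate is an exact repeat of (participant, date, drug, quantity).
    Idempotent: applying twice equals applying once.
    """
    key = ["participant_id", "dispense_date", "drug", "days_supplied"]
    dup = df.duplicated(subset=key, keep="first")
    if issues is not None:
        for idx in df.index[dup]:
            row = df.loc[idx]
            issues.append(RowIssue(
                "dispensing", int(idx) + 2,
                f"duplicate dispensing removed ({row['participant_id']}, "
                f"{row['dispense_date'].date()}, {row['drug']}, {row['days_supplied']})",
            ))
    return df[~dup]


def _read_csv(paths: Mapping[str, Path], stream: str) -> pd.DataFrame:
    path = Path(paths[stream])
    if not path.exists():
        raise FileNotFoundError(f"input file for stream {stream!r} not found: {path}")
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, stream)
    return df.reset_index(drop=True)


def default_paths(in_dir: str | Path) -> dict[str, Path]:
    in_dir = Path(in_dir)
    return {stream: in_dir / f"{stream}.csv" for stream in SCHEMAS}


def read_cohort(
    paths: str | Path | Mapping[str, Path],
    config: AnalysisConfig | None = None,
) -> Cohort:
    """Load, validate and normalise all input streams.

    ``paths`` may be a directory (files named ``<stream>.csv``) or an explicit
    stream->path mapping.  Raises :class:`SchemaError` for missing columns and
    ``ValueError`` for duplicate participant ids; row-level problems are
    collected on the returned cohort.
    """
    config = config or AnalysisConfig()
    if not isinstance(paths, Mapping):
        paths = default_paths(paths)
    issues: list[RowIssue] = []

    participants = _read_csv(paths, "participants")
    participants = _parse_dates(participants, "participants", issues,
                                required=["randomisation_date"])
    if participants["participant_id"].duplicated().any():
        dupes = participants.loc[
            participants["participant_id"].duplicated(), "participant_id"
        ].tolist()
        raise ValueError(f"duplicate participant_id in participants: {dupes}")
    participants = _reject(
        participants, ~participants["sex"].isin(SEX_VALUES),
        "participants", "invalid sex", issues)
    participants = _reject(
        participants, ~participants["care_status"].isin(CARE_STATUS_VALUES),
        "participants", "invalid care_status", issues)
    participants = _reject(
        participants, pd.to_numeric(participants["age_years"], errors="coerce") <= 0,
        "participants", "age_years must be > 0", issues)
    participants = _reject(
        participants, pd.to_numeric(participants["baseline_cd4"], errors="coerce") < 0,
        "participants", "baseline_cd4 must be >= 0", issues)
    bad_eoc = (
        participants["end_of_care_date"].notna()
        & (participants["end_of_care_date"] < participants["randomisation_date"])
    )
    participants = _reject(participants, bad_eoc, "participants",
                           "end_of_care_date precedes randomisation_date", issues)
    participants = participants.reset_index(drop=True)
    rand_dates = participants.set_index("participant_id")["randomisation_date"]

    dispensing = _read_csv(paths, "dispensing")
    dispensing = _parse_dates(dispensing, "dispensing", issues, required=["dispense_date"])
    dispensing["days_supplied"] = pd.to_numeric(dispensing["days_supplied"], errors="coerce")
    dispensing = _reject(dispensing, ~(dispensing["days_supplied"] >= 1),
                         "dispensing", "days_supplied must be >= 1", issues)
    dispensing["days_supplied"] = dispensing["days_supplied"].astype(int)
    dispensing = _reject(dispensing, ~dispensing["drug"].isin(DRUG_VALUES),
                         "dispensing", "invalid drug", issues)
    dispensing = dedupe_dispensing(dispensing, issues)
    pre_rand = dispensing["participant_id"].map(rand_dates).notna() & (
        dispensing["dispense_date"] < dispensing["participant_id"].map(rand_dates)
    )
    dispensing = _reject(dispensing, pre_rand, "dispensing",
                         "dispense_date precedes randomisation", issues)

    eamd = _read_csv(paths, "eamd_events")
    eamd = _parse_dates(eamd, "eamd_events", issues, required=["timestamp"])
    eamd = _reject(eamd, ~eamd["event_type"].isin(EAMD_EVENT_TYPES),
                   "eamd_events", "invalid event_type", issues)
    eamd["battery_voltage"] = pd.to_numeric(eamd["battery_voltage"], errors="coerce")
    eamd = _reject(eamd, ~(eamd["battery_voltage"] >= 0),
                   "eamd_events", "battery_voltage must be >= 0", issues)

    pill = _read_csv(paths, "pill_returns")
    pill = _parse_dates(pill, "pill_returns", issues,
                        required=["count_date", "last_dispense_date"])
    for col in ("tablets_dispensed_since_last", "tablets_returned", "doses_per_day"):
        pill[col] = pd.to_numeric(pill[col], errors="coerce")
    pill = _reject(pill, ~(pill["tablets_returned"] >= 0),
                   "pill_returns", "tablets_returned must be >= 0", issues)
    pill = _reject(pill, ~(pill["count_date"] > pill["last_dispense_date"]),
                   "pill_returns", "count_date must follow last_dispense_date", issues)

    sr = _read_csv(paths, "self_report")
    sr = _parse_dates(sr, "self_report", issues, required=["visit_date"])
    for col in ("took_day1", "took_day2", "took_day3"):
        sr[col] = _parse_bool(sr[col])
    incomplete = sr[["took_day1", "took_day2", "took_day3"]].isna().any(axis=1)
    sr = _reject(sr, incomplete, "self_report", "incomplete 3-day recall", issues)

    efv = _read_csv(paths, "efv_concentrations")
    efv = _parse_dates(efv, "efv_concentrations", issues, required=["sample_date"])
    efv["efv_mg_per_l"] = pd.to_numeric(efv["efv_mg_per_l"], errors="coerce")
    efv = _reject(efv, ~(efv["efv_mg_per_l"] >= 0),
                  "efv_concentrations", "efv_mg_per_l must be >= 0", issues)

    labs = _read_csv(paths, "labs")
    labs = _parse_dates(labs, "labs", issues, required=["sample_date"])
    labs["hiv_rna_copies_per_ml"] = pd.to_numeric(
        labs["hiv_rna_copies_per_ml"], errors="coerce")
    labs = _reject(labs, ~(labs["hiv_rna_copies_per_ml"] >= 0),
                   "labs", "hiv_rna_copies_per_ml must be >= 0", issues)

    genotypes = _read_csv(paths, "genotypes")
    genotypes = _parse_dates(genotypes, "genotypes", issues, required=["sample_date"])
    genotypes["amplified"] = _parse_bool(genotypes["amplified"])
    genotypes["mutations"] = genotypes["mutations"].apply(parse_mutations)
    inconsistent = (~genotypes["amplified"].fillna(False)) & (
        genotypes["mutations"].str.len() > 0
    )
    for idx in genotypes.index[inconsistent]:
        issues.append(RowIssue("genotypes", int(idx) + 2,
                               "mutations listed on unamplified sample; cleared"))
    genotypes.loc[inconsistent, "mutations"] = genotypes.loc[inconsistent, "mutations"].apply(
        lambda _: [])

    frames = {
        "participants": participants,
        "dispensing": dispensing,
        "eamd_events": eamd,
        "pill_returns": pill,
        "self_report": sr,
        "efv_concentrations": efv,
        "labs": labs,
        "genotypes": genotypes,
    }
    for name, frame in frames.items():
        if name == "participants":
            continue
        key = _SORT_KEYS[name]
        frames[name] = frame.sort_values(
            ["participant_id", key], kind="stable"
        ).reset_index(drop=True)

    known = set(participants["participant_id"])
    for name, frame in frames.items():
        if name == "participants":
            continue
        orphan = ~frame["participant_id"].isin(known)
        if orphan.any():
            for pid in frame.loc[orphan, "participant_id"].unique():
                issues.append(RowIssue(name, None, f"unknown participant_id {pid!r}"))
            frames[name] = frame[~orphan].reset_index(drop=True)

    no_eamd = known - set(frames["eamd_events"]["participant_id"])
    for pid in sorted(no_eamd):
        issues.append(RowIssue("eamd_events", None, f"no EAMD events for {pid!r}"))

    if issues:
        log.warning("read_cohort: %d row-level issue(s)", len(issues))
    return Cohort(issues=issues, **frames)


def parse_mutations(raw: object) -> list[str]:
    """Parse a semicolon-separated mutation list (e.g. ``"K65R;M184V"``)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    if isinstance(raw, list):
        return [str(m).strip() for m in raw if str(m).strip()]
    text = str(raw).strip()
    if not text:
        return []
    return [m.strip() for m in text.split(";") if m.strip()]


def format_mutations(mutations: Iterable[str]) -> str:
    return ";".join(mutations)


def write_outputs(
    estimates: pd.DataFrame,
    model_report: pd.DataFrame | None,
    out_dir: str | Path,
    roc_points: Mapping[tuple[str, str], pd.DataFrame] | None = None,
    run_info: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write the tidy estimate table, model report, ROC point files and run log.

    Returns a name->path mapping of everything written.  Floating point
    columns are written at full precision so a write/read round trip is exact
    to the printed representation.
    """
    if estimates is None or len(estimates) == 0:
        raise ValueError("write_outputs: estimates table is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    est_path = out_dir / "adherence_estimates.csv"
    est = estimates.copy()
    for col in ("window_start", "window_end"):
        if col in est.columns:
            est[col] = pd.to_datetime(est[col]).dt.strftime("%Y-%m-%d")
    est.to_csv(est_path, index=False)
    written["adherence_estimates"] = est_path

    if model_report is not None and len(model_report):
        rep_path = out_dir / "model_report.csv"
        model_report.to_csv(rep_path, index=False)
        written["model_report"] = rep_path

    for (method, landmark), points in (roc_points or {}).items():
        path = out_dir / f"roc_points_{method.lower()}_{landmark}.csv"
        points.to_csv(path, index=False)
        written[f"roc_{method}_{landmark}"] = path

    if run_info is not None:
        log_path = out_dir / "run_log.txt"
        lines = [f"{k}: {v}" for k, v in run_info.items()]
        log_path.write_text("\n".join(lines) + "\n")
        written["run_log"] = log_path
    return written


def cohort_field_names(type_name: str) -> tuple[str, ...]:
    """Columns of one input stream (public, for generators and docs)."""
    return SCHEMAS[type_name]
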