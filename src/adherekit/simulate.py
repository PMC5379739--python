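"""Seeded synthetic cohort generator for the adherence pipeline.

The generator produces every input stream the pipeline reads — participants,
pharmacy dispensing, electronic-monitor events, clinic pill returns, 3-day
recall, efavirenz concentrations, labs and genotypes — together with the
ground-truth daily dosing record, so every estimator can be checked against
truth.

Structure of the simulation
---------------------------
* Daily pill taking is a two-state (dosing/gap) Markov chain per participant,
  with latent adherence classes (high/medium/low persistence).  Clustered
  gaps, not i.i.d. misses, are what make refill-gap and electronic measures
  disagree realistically.
* Dispensing is supply-driven: participants return for a refill around the
  day their pack runs out (28-day supplies through the week-16 visit,
  56-day supplies after), with class-dependent early-refill jitter and
  occasional late episodes of one to four weeks.
* Measurement processes add the biases seen in practice: pocket doses the
  monitor never sees, dead-battery episodes censoring about 10% of monitor
  days, optimistic self-report, occasional pill dumping, and a white-coat
  boost to drug concentrations on the visit eve.
* Landmark outcomes (virological failure; resistance among amplified
  failures) follow logistic models in true cumulative adherence and baseline
  covariates, parameterised per 10% adherence.

Everything is driven by one ``numpy`` generator; the same seed and config
reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import WEEK16, WEEK48
from .io import Cohort, SCHEMAS, format_mutations

BASE_DATE = pd.Timestamp("2012-07-12")

NNRTI_MUTATIONS = ("K103N", "V106M", "Y181C", "G190A")
MINOR_MUTATIONS = ("V90I", "E138A", "V179D")


@dataclass(frozen=True)
class AdherenceClass:
    """Latent dosing class: two-state Markov chain plus visit behaviour.

    ``p_dose_to_dose`` is the probability of dosing tomorrow given dosing
    today; ``p_gap_to_dose`` of resuming after a missed day.  The long-run
    (stationary) adherence is p_gd / (p_gd + 1 - p_dd).
    """

    name: str
    weight: float
    p_dose_to_dose: float
    p_gap_to_dose: float
    late_episode_prob: float  # chance a refill is late by 1-4 weeks
    refill_jitter: tuple[int, int]  # usual refill timing relative to stock-out

    @property
    def stationary_adherence(self) -> float:
        a = self.p_gap_to_dose
        b = 1.0 - self.p_dose_to_dose
        return a / (a + b)


DEFAULT_CLASSES = (
    AdherenceClass("high", 0.50, 0.990, 0.60, 0.02, (-4, 2)),
    AdherenceClass("medium", 0.28, 0.960, 0.25, 0.08, (-4, 4)),
    AdherenceClass("low", 0.22, 0.900, 0.12, 0.20, (-3, 6)),
)


@dataclass(frozen=True)
class OutcomeParams:
    """Logistic outcome link, parameterised per 10% true adherence.

    Intercepts are on the linear predictor at the covariate centre
    (age 34.5 y, CD4 225 cells/mm^3, log VL 4.9) and adherence 0; slopes are
    per year of age, per 100 CD4 cells, per log10 copies/ml, and per 10
    adherence points.  Defaults give week-48 failure around 13% and week-16
    failure around 10% under the default adherence mix.
    """

    beta0: Mapping[str, float] = field(
        default_factory=lambda: {WEEK16: 0.50, WEEK48: 0.90})
    beta_adherence_per_10pct: float = math.log(0.70)
    beta_age: float = -0.02
    beta_cd4_per_100: float = -0.20
    beta_logvl: float = 0.30
    amplification_prob: float = 0.88
    resistance_beta0: float = 1.2
    resistance_beta_adherence_per_10pct: float = -0.5
    resistance_adherence_centre: float = 60.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All generator dials, with defaults emulating a high-adherence
    first-line ART cohort of 230 participants followed for 48 weeks."""

    n_participants: int = 230
    follow_up_days: int = 336
    classes: tuple[AdherenceClass, ...] = DEFAULT_CLASSES
    # measurement layer
    p_pocket_dose: float = 0.08
    dead_battery_fraction: float = 0.10
    dead_battery_mean_days: float = 7.0
    battery_voltage_mean: float = 3900.0
    battery_voltage_sd: float = 60.0
    battery_voltage_dead: float = 3400.0
    sr_yes_bias: float = 0.85
    pill_dumping_prob: float = 0.10
    pill_dump_keep_frac: float = 0.4
    white_coat_boost: float = 0.80
    efv_median_mg_per_l: float = 2.3
    efv_recent_slope_log10: float = 0.45
    efv_between_subject_sd_log10: float = 0.18
    efv_undetectable_prob: float = 0.5
    # visit/attrition layer
    care_status_probs: Mapping[str, float] = field(default_factory=lambda: {
        "in_care": 0.808, "transferred": 0.070, "died": 0.035,
        "ltfu": 0.083, "withdrew": 0.004})
    p_vl_drawn: Mapping[str, float] = field(
        default_factory=lambda: {WEEK16: 0.75, WEEK48: 0.95})
    p_study_visit: float = 0.90
    # baseline covariates
    age_mean: float = 34.5
    age_sd: float = 9.1
    cd4_median: float = 225.0
    cd4_log_sd: float = 0.57
    logvl_mean: float = 4.9
    logvl_sd: float = 0.75
    outcome: OutcomeParams = field(default_factory=OutcomeParams)

    def __post_init__(self):
        probs = [c.weight for c in self.classes] + [
            self.p_pocket_dose, self.dead_battery_fraction, self.sr_yes_bias,
            self.pill_dumping_prob, self.white_coat_boost, self.p_study_visit,
            *self.care_status_probs.values(), *self.p_vl_drawn.values()]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(c.weight for c in self.classes) - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")

    @property
    def horizon_days(self) -> int:
        # dosing is simulated a little past nominal follow-up so jittered
        # week-48 visits always have truth behind them
        return self.follow_up_days + 28

    def null_outcomes(self) -> "GeneratorConfig":
        """Copy with adherence decoupled from outcome (type-I-error runs)."""
        return replace(self, outcome=replace(
            self.outcome, beta_adherence_per_10pct=0.0,
            resistance_beta_adherence_per_10pct=0.0))


@dataclass
class SimulatedCohort:
    """Generated cohort, its ground truth and the generator bookkeeping."""

    cohort: Cohort
    truth: pd.DataFrame  # long: participant_id, day, dose_taken, latent_class
    dose_matrix: np.ndarray  # n x horizon, bool; days past end-of-care are 0
    end_day: np.ndarray
    latent_class: np.ndarray
    config: GeneratorConfig
    seed: int


LANDMARK_WINDOW_DAYS = {WEEK16: (84, 140, 112), WEEK48: (224, 448, 336)}


def _landmark_vl_day(visits: Sequence[tuple[int, int]], landmark: str) -> int | None:
    """Blood-draw day for a landmark: the attended clinic visit inside the
    landmark window closest to the nominal day (None if all missed)."""
    lo, hi, nominal = LANDMARK_WINDOW_DAYS[landmark]
    candidates = [d for d, _ in visits if lo <= d <= hi]
    if not candidates:
        return None
    return min(candidates, key=lambda d: (abs(d - nominal), d))


def _dead_battery_days(
    rng, n_days: int, cfg: GeneratorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Alternating-renewal dead-battery episodes; stationary fraction equals
    the configured rate.  Returns (dead-day mask, episode-start mask)."""
    f, L = cfg.dead_battery_fraction, cfg.dead_battery_mean_days
    if f <= 0 or n_days == 0:
        zeros = np.zeros(n_days, dtype=bool)
        return zeros, zeros.copy()
    start_rate = f / ((1.0 - f) * L)
    dead = np.zeros(n_days, dtype=bool)
    first = np.zeros(n_days, dtype=bool)
    t = 0
    while True:
        t += int(rng.geometric(start_rate))
        if t >= n_days:
            break
        length = int(rng.geometric(1.0 / L))
        first[t] = True
        dead[t:min(t + length, n_days)] = True
        t += length
    # first[] marks episode starts where the device still sends one low-
    # voltage heartbeat before going silent
    return dead, first


def generate(config: GeneratorConfig | None = None, seed: int = 0,
             out_dir: str | Path | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort; optionally write the input CSVs.

    Deterministic given ``(config, seed)``.  When ``out_dir`` is given the
    eight input CSVs plus ``truth.csv`` are written in the documented normal
    form so ``read_cohort(out_dir)`` reloads the cohort.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_participants
    horizon = cfg.horizon_days

    pids = np.array([f"P{i + 1:04d}" for i in range(n)])
    class_idx = rng.choice(len(cfg.classes), size=n,
                           p=[c.weight for c in cfg.classes])
    classes = [cfg.classes[i] for i in class_idx]

    rand_offsets = rng.integers(0, 270, size=n)
    rand_dates = BASE_DATE + pd.to_timedelta(rand_offsets, unit="D")

    # baseline covariates
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 16, 75)
    cd4 = np.exp(rng.normal(math.log(cfg.cd4_median), cfg.cd4_log_sd, n))
    logvl = np.clip(rng.normal(cfg.logvl_mean, cfg.logvl_sd, n), 2.5, 6.5)
    sex = rng.choice(["female", "male"], size=n, p=[0.65, 0.35])

    # attrition
    statuses = list(cfg.care_status_probs)
    care_status = rng.choice(statuses, size=n,
                             p=[cfg.care_status_probs[s] for s in statuses])
    end_day = np.where(
        care_status == "in_care", horizon,
        rng.integers(30, cfg.follow_up_days, size=n)).astype(int)

    # daily dosing: vectorised two-state Markov chain
    p_dd = np.array([c.p_dose_to_dose for c in classes])
    p_gd = np.array([c.p_gap_to_dose for c in classes])
    dose = np.zeros((n, horizon), dtype=bool)
    dose[:, 0] = True
    for t in range(1, horizon):
        p = np.where(dose[:, t - 1], p_dd, p_gd)
        dose[:, t] = rng.random(n) < p
    day_grid = np.arange(horizon)
    dose &= day_grid[None, :] < end_day[:, None]
    cum_dose = np.cumsum(dose, axis=1)

    # dispensing: refills are scheduled off the previous supply (come back
    # when the pack runs out), so habitual early attenders accumulate
    # surplus (PR-average > 100%) and late episodes open possession gaps.
    # Poor adherers drift late in proportion to how long their pills
    # actually last (refill_tracking is how strongly a participant times
    # refills by true consumption rather than the calendar), which is what
    # makes refill measures informative about dosing at all.  Supplies are
    # monthly (28 d) until the week-16 visit, two-monthly after.
    disp_rows: list[tuple[str, int, int]] = []
    per_part_disp: list[list[tuple[int, int]]] = []
    refill_tracking = rng.beta(2.0, 3.0, size=n)
    for i in range(n):
        cls = classes[i]
        jlo, jhi = cls.refill_jitter
        pi = max(cls.stationary_adherence, 0.3)
        visits: list[tuple[int, int]] = []
        day = 0
        while day < end_day[i]:
            supply = 28 if day < 110 else 56
            visits.append((day, supply))
            slack = refill_tracking[i] * supply * (1.0 / pi - 1.0)
            if rng.random() < cls.late_episode_prob:
                delay = int(rng.integers(7, 29))
            else:
                delay = int(rng.integers(jlo, jhi + 1))
            day = max(day + supply + int(round(slack)) + delay, day + 1)
        per_part_disp.append(visits)
        disp_rows.extend((pids[i], d, s) for d, s in visits)

    # landmark visits, labs, outcomes, genotypes and visit-linked streams
    op = cfg.outcome
    lab_rows, sr_rows, pill_rows, efv_rows, geno_rows = [], [], [], [], []
    efv_subject_effect = rng.normal(0.0, cfg.efv_between_subject_sd_log10, n)
    for i in range(n):
        # baseline lab
        lab_rows.append((pids[i], 0, 10 ** logvl[i], cd4[i]))
        for landmark in (WEEK16, WEEK48):
            vl_day = _landmark_vl_day(per_part_disp[i], landmark)
            if vl_day is None or vl_day >= end_day[i]:
                continue
            if rng.random() >= cfg.p_vl_drawn[landmark]:
                continue
            adh = 100.0 * cum_dose[i, vl_day - 1] / vl_day
            lp = (op.beta0[landmark]
                  + op.beta_adherence_per_10pct * adh / 10.0
                  + op.beta_age * (age[i] - cfg.age_mean)
                  + op.beta_cd4_per_100 * (cd4[i] - cfg.cd4_median) / 100.0
                  + op.beta_logvl * (logvl[i] - cfg.logvl_mean))
            failed = rng.random() < 1.0 / (1.0 + math.exp(-lp))
            threshold = 400.0 if landmark == WEEK16 else 40.0
            if failed:
                log_lo = math.log10(threshold + 1)
                vl = 10 ** rng.uniform(log_lo, 5.0)
            elif rng.random() < 0.6:
                vl = 0.0
            else:
                vl = rng.uniform(1.0, threshold * 0.9)
            lab_rows.append((pids[i], vl_day, vl, cd4[i] + rng.normal(120, 60)))

            if failed and vl > 500.0:
                amplified = rng.random() < op.amplification_prob
                mutations: list[str] = []
                if amplified:
                    lp_r = (op.resistance_beta0
                            + op.resistance_beta_adherence_per_10pct
                            * (adh - op.resistance_adherence_centre) / 10.0)
                    resistant = rng.random() < 1.0 / (1.0 + math.exp(-lp_r))
                    if resistant:
                        mutations.append(str(rng.choice(NNRTI_MUTATIONS)))
                        if rng.random() < 0.5:
                            mutations.append("K65R")
                        if rng.random() < 0.35:
                            mutations.append("M184V")
                    elif rng.random() < 0.5:
                        mutations.append(str(rng.choice(MINOR_MUTATIONS)))
                geno_rows.append((pids[i], vl_day, mutations, amplified))

            # clinic pill count: last dispensing strictly before the visit
            prior = [(d, s) for d, s in per_part_disp[i] if d < vl_day]
            if prior:
                disp_day, supply = prior[-1]
                taken = int(cum_dose[i, vl_day - 1] - (cum_dose[i, disp_day - 1]
                                                       if disp_day > 0 else 0))
                returned = max(0, supply - taken)
                if rng.random() < cfg.pill_dumping_prob:
                    returned = int(rng.binomial(returned, cfg.pill_dump_keep_frac))
                pill_rows.append((pids[i], vl_day, supply, returned, disp_day, 1.0))

            if rng.random() < cfg.p_study_visit:
                answers = []
                for back in (1, 2, 3):
                    took = bool(dose[i, vl_day - back])
                    if not took and rng.random() < cfg.sr_yes_bias:
                        took = True
                    answers.append(took)
                sr_rows.append((pids[i], vl_day, *answers))

                recent = int(dose[i, vl_day - 3:vl_day].sum())
                if recent == 0 and rng.random() < cfg.white_coat_boost:
                    recent = 1  # pre-visit dose the monitor-period truth missed
                if recent == 0:
                    conc = 0.0 if rng.random() < cfg.efv_undetectable_prob else float(
                        np.exp(rng.normal(math.log(0.15), 0.6)))
                else:
                    log10c = (math.log10(cfg.efv_median_mg_per_l)
                              + cfg.efv_recent_slope_log10 * (recent / 3.0 - 1.0)
                              + efv_subject_effect[i] + rng.normal(0, 0.10))
                    conc = float(10 ** log10c)
                efv_rows.append((pids[i], vl_day, round(conc, 3), "20:00"))

    # EAMD event streams
    ev_pid, ev_ts, ev_type, ev_volt = [], [], [], []
    for i in range(n):
        nd = int(end_day[i])
        if nd <= 0:
            continue
        dead, first_dead = _dead_battery_days(rng, nd, cfg)
        pocket = rng.random(nd) < cfg.p_pocket_dose
        opening = dose[i, :nd] & ~pocket & ~dead
        heartbeat = ~dead | first_dead
        days = np.flatnonzero(heartbeat)
        volt = np.round(rng.normal(cfg.battery_voltage_mean,
                                   cfg.battery_voltage_sd, len(days)))
        volt[first_dead[days]] = cfg.battery_voltage_dead
        hb_seconds = days * 86400 + (6 + 6) * 3600  # heartbeat at 12:00
        ev_pid.append(np.repeat(pids[i], len(days)))
        ev_ts.append(rand_offsets[i] * 86400 + hb_seconds)
        ev_type.append(np.repeat("heartbeat", len(days)))
        ev_volt.append(volt)

        odays = np.flatnonzero(opening)
        hours = np.clip(rng.normal(14.0, 2.0, len(odays)), 0.25, 23.75)
        op_seconds = odays * 86400 + ((6 + hours) * 3600).astype(int)
        ovolt = np.round(rng.normal(cfg.battery_voltage_mean,
                                    cfg.battery_voltage_sd, len(odays)))
        ev_pid.append(np.repeat(pids[i], len(odays)))
        ev_ts.append(rand_offsets[i] * 86400 + op_seconds)
        ev_type.append(np.repeat("opening", len(odays)))
        ev_volt.append(ovolt)

    # ---- assemble frames in the documented normal form -------------------
    participants = pd.DataFrame({
        "participant_id": pids,
        "sex": sex,
        "age_years": np.round(age, 1),
        "baseline_cd4": np.round(cd4, 0),
        "baseline_log10_vl": np.round(logvl, 2),
        "randomisation_date": rand_dates,
        "end_of_care_date": [
            rand_dates[i] + pd.Timedelta(days=int(end_day[i]))
            if care_status[i] != "in_care" else pd.NaT for i in range(n)],
        "care_status": care_status,
    })

    def _dates(pid_days: Sequence[tuple], idx_map: Mapping[str, int], col: int):
        return [rand_dates[idx_map[r[0]]] + pd.Timedelta(days=int(r[col]))
                for r in pid_days]

    idx_map = {pid: i for i, pid in enumerate(pids)}
    dispensing = pd.DataFrame({
        "participant_id": [r[0] for r in disp_rows],
        "dispense_date": _dates(disp_rows, idx_map, 1),
        "drug": "efavirenz",
        "days_supplied": [r[2] for r in disp_rows],
    })
    if ev_pid:
        eamd_events = pd.DataFrame({
            "participant_id": np.concatenate(ev_pid),
            "timestamp": BASE_DATE + pd.to_timedelta(
                np.concatenate(ev_ts), unit="s"),
            "event_type": np.concatenate(ev_type),
            "battery_voltage": np.concatenate(ev_volt).astype(int),
        })
    else:  # pragma: no cover - empty cohort corner
        eamd_events = pd.DataFrame(columns=list(SCHEMAS["eamd_events"]))
    pill_returns = pd.DataFrame({
        "participant_id": [r[0] for r in pill_rows],
        "count_date": _dates(pill_rows, idx_map, 1),
        "drug": "efavirenz",
        "tablets_dispensed_since_last": [r[2] for r in pill_rows],
        "tablets_returned": [r[3] for r in pill_rows],
        "last_dispense_date": _dates(pill_rows, idx_map, 4),
        "doses_per_day": [r[5] for r in pill_rows],
    })
    self_report = pd.DataFrame({
        "participant_id": [r[0] for r in sr_rows],
        "visit_date": _dates(sr_rows, idx_map, 1),
        "took_day1": [r[2] for r in sr_rows],
        "took_day2": [r[3] for r in sr_rows],
        "took_day3": [r[4] for r in sr_rows],
    })
    efv = pd.DataFrame({
        "participant_id": [r[0] for r in efv_rows],
        "sample_date": _dates(efv_rows, idx_map, 1),
        "efv_mg_per_l": [r[2] for r in efv_rows],
        "reported_last_dose_time": [r[3] for r in efv_rows],
    })
    labs = pd.DataFrame({
        "participant_id": [r[0] for r in lab_rows],
        "sample_date": _dates(lab_rows, idx_map, 1),
        "hiv_rna_copies_per_ml": np.round([r[2] for r in lab_rows], 1),
        "cd4": np.round([r[3] for r in lab_rows], 0),
    })
    genotypes = pd.DataFrame({
        "participant_id": [r[0] for r in geno_rows],
        "sample_date": _dates(geno_rows, idx_map, 1),
        "mutations": [r[2] for r in geno_rows],
        "amplified": [r[3] for r in geno_rows],
    })
    if genotypes.empty:
        genotypes = pd.DataFrame(columns=list(SCHEMAS["genotypes"]))
        genotypes["mutations"] = genotypes["mutations"].astype(object)

    sort_keys = {"dispensing": "dispense_date", "eamd_events": "timestamp",
                 "pill_returns": "count_date", "self_report": "visit_date",
                 "efv_concentrations": "sample_date", "labs": "sample_date",
                 "genotypes": "sample_date"}
    frames = {"participants": participants, "dispensing": dispensing,
              "eamd_events": eamd_events, "pill_returns": pill_returns,
              "self_report": self_report, "efv_concentrations": efv,
              "labs": labs, "genotypes": genotypes}
    for name, key in sort_keys.items():
        if len(frames[name]):
            frames[name] = frames[name].sort_values(
                ["participant_id", key], kind="stable").reset_index(drop=True)

    truth = pd.DataFrame({
        "participant_id": np.repeat(pids, end_day),
        "day": np.concatenate([np.arange(d) for d in end_day]),
        "dose_taken": np.concatenate(
            [dose[i, :end_day[i]].astype(int) for i in range(n)]),
        "latent_class": np.repeat([c.name for c in classes], end_day),
    })

    cohort = Cohort(**frames)
    sim = SimulatedCohort(cohort=cohort, truth=truth, dose_matrix=dose,
                          end_day=end_day, latent_class=class_idx,
                          config=cfg, seed=seed)
    if out_dir is not None:
        write_cohort_csvs(sim, out_dir)
    return sim


def write_cohort_csvs(sim: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the eight input CSVs plus truth.csv in the normal form."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    date_cols = {"participants": ["randomisation_date", "end_of_care_date"],
                 "dispensing": ["dispense_date"],
                 "pill_returns": ["count_date", "last_dispense_date"],
                 "self_report": ["visit_date"],
                 "efv_concentrations": ["sample_date"],
                 "labs": ["sample_date"], "genotypes": ["sample_date"]}
    for name in SCHEMAS:
        frame = sim.cohort.stream(name).copy()
        for col in date_cols.get(name, []):
            frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
        if name == "eamd_events":
            frame["timestamp"] = pd.to_datetime(
                frame["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        if name == "genotypes":
            frame["mutations"] = frame["mutations"].apply(format_mutations)
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path
    truth_path = out_dir / "truth.csv"
    sim.truth.to_csv(truth_path, index=False)
    written["truth"] = truth_path
    return written


def truth_adherence(truth: pd.DataFrame, participant_id: str,
                    n_days: int) -> float | None:
    """Ground-truth cumulative adherence (%) over days ``[0, n_days)``."""
    rows = truth[(truth["participant_id"] == participant_id)
                 & (truth["day"] < n_days)]
    if rows.empty:
        return None
    return 100.0 * float(rows["dose_taken"].mean())


def stationary_adherence(p_dose_to_dose: float, p_gap_to_dose: float) -> float:
    """Closed-form long-run adherence of the two-state dosing chain."""
    a, b = p_gap_to_dose, 1.0 - p_dose_to_dose
    return a / (a + b)


def simulate_outcome_layer(
    n: int,
    seed: int,
    or_per_10pct: float = 0.80,
    beta0: float = 0.28,
    classes: tuple[AdherenceClass, ...] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Outcome-layer-only cohort: (adherence %, binary outcome) pairs.

    Draws true adherence from the class mixture's stationary distribution
    (plus small within-subject sampling noise) and the outcome from the
    exact logistic link ``logit p = beta0 + log(or_per_10pct) * adh/10``.
    Used for parameter-recovery and type-I-error studies where the full
    measurement layer is irrelevant.
    """
    rng = np.random.default_rng(seed)
    weights = [c.weight for c in classes]
    idx = rng.choice(len(classes), size=n, p=weights)
    pi = np.array([c.stationary_adherence for c in classes])[idx]
    adherence = np.clip(rng.normal(100.0 * pi, 4.0), 0.0, 100.0)
    lp = beta0 + math.log(or_per_10pct) * adherence / 10.0
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
    return pd.DataFrame({"adherence": adherence, "y": y.astype(int)})
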