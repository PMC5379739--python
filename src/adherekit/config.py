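"""Analysis configuration: landmark windows, device thresholds, anchor drugs.

All tunables that the estimators and outcome models consume live here, so a
single structured config file (YAML) drives a whole pipeline run.  Values are
calendar-day offsets from each participant's randomisation date; day
arithmetic is half-open ``[start, end)`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

WEEK16 = "week16"
WEEK48 = "week48"
LANDMARKS = (WEEK16, WEEK48)


@dataclass(frozen=True)
class LandmarkSpec:
    """One landmark visit and its per-protocol evaluation window.

    ``window_start_day``/``window_end_day`` are inclusive day offsets from
    randomisation within which a viral load qualifies; ``nominal_day`` is the
    scheduled visit day used to pick between multiple in-window results;
    ``failure_threshold`` is the HIV-RNA cut-off (copies/ml) defining
    virological failure at this landmark.
    """

    name: str
    window_start_day: int
    window_end_day: int
    nominal_day: int
    failure_threshold: float


DEFAULT_LANDMARKS: Mapping[str, LandmarkSpec] = {
    WEEK16: LandmarkSpec(WEEK16, 84, 140, 112, 400.0),
    WEEK48: LandmarkSpec(WEEK48, 224, 448, 336, 40.0),
}

ANCHOR_DRUGS = ("efavirenz", "nevirapine", "lopinavir_r")


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings shared by readers, estimators and outcome models.

    battery_threshold
        Device battery reading (integer device units, mV scale) below which a
        monitor day is censored as a dead-battery day.  Default 3660.
    efv_log_floor_mg_per_l
        Floor applied to efavirenz concentrations before log10, so
        undetectable (0) samples map to a finite model input.
    genotype_vl_threshold
        Minimum HIV-RNA (copies/ml) for genotype amplification eligibility.
    anchor_drugs
        Drugs whose dispensing/tablet counts enter refill and pill-count
        adherence (the once-daily anchor of the regimen).
    """

    battery_threshold: int = 3660
    efv_log_floor_mg_per_l: float = 0.05
    genotype_vl_threshold: float = 500.0
    anchor_drugs: tuple[str, ...] = ANCHOR_DRUGS
    doses_per_day_default: float = 1.0
    landmarks: Mapping[str, LandmarkSpec] = field(
        default_factory=lambda: dict(DEFAULT_LANDMARKS)
    )

    def landmark(self, name: str) -> LandmarkSpec:
        try:
            return self.landmarks[name]
        except KeyError:
            raise KeyError(
                f"unknown landmark {name!r}; expected one of {sorted(self.landmarks)}"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config file; keys absent from the file keep their defaults.

        Recognised keys: battery_threshold, efv_log_floor_mg_per_l,
        genotype_vl_threshold, anchor_drugs, doses_per_day, and
        landmark_windows (mapping landmark -> [start_day, end_day]).
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        simple = {
            "battery_threshold": "battery_threshold",
            "efv_log_floor_mg_per_l": "efv_log_floor_mg_per_l",
            "genotype_vl_threshold": "genotype_vl_threshold",
            "doses_per_day": "doses_per_day_default",
        }
        kwargs = {}
        for key, attr in simple.items():
            if key in raw:
                kwargs[attr] = raw[key]
        if "anchor_drugs" in raw:
            kwargs["anchor_drugs"] = tuple(raw["anchor_drugs"])
        if "landmark_windows" in raw:
            landmarks = dict(DEFAULT_LANDMARKS)
            for name, (start, end) in raw["landmark_windows"].items():
                base = landmarks[name]
                landmarks[name] = replace(
                    base, window_start_day=int(start), window_end_day=int(end)
                )
            kwargs["landmarks"] = landmarks
        return replace(cfg, **kwargs)
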