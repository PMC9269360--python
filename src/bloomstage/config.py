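"""Run configuration: every fixed constant of the pipeline in one place."""
from __future__ import annotations

import calendar
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Tunable constants of the staging/calibration/ice pipeline.

    Defaults encode the published protocol: a station-year needs at least 6
    ice-free satellite observations, no gap longer than 25 days, and at least
    3 observations inside the mid-summer window DOY 174-219; observations
    under more than 15% ice concentration are masked; a bloom must rise at
    least 0.5 mg/m^3 above its starting minimum; breakup is the first 2-day
    run below 15% ice; a spring open-water run of more than 5 consecutive
    zero-ice days (Mar 1 - May 1) marks a low-ice year.
    """

    min_obs_per_year: int = 6
    max_gap_days: int = 25
    window_doys: tuple[int, int] = (174, 219)
    min_obs_in_window: int = 3
    ice_mask_pct: float = 15.0
    bloom_rise_min: float = 0.5
    threshold_range: tuple[int, int] = (0, 100)
    breakup_pct: float = 15.0
    breakup_run_days: int = 2
    openwater_run_days_exclusive: int = 5  # "more than" semantics: LOW needs >5
    alpha: float = 0.05
    seed: int = 0
    # optional seasonal bounds for the QC gap rule; None = gaps between
    # consecutive retained observations only
    season_bounds: tuple[int, int] | None = None
    # smoothing knobs (span resolved per-series in phenology)
    lowess_min_points: int = 7
    lowess_frac: float = 0.30
    lowess_robust_iters: int = 0
    # AMOC changepoint penalty scale: penalty = amoc_penalty_scale * ln(n) * var
    amoc_penalty_scale: float = 2.0

    @staticmethod
    def openwater_window(year: int) -> tuple[int, int]:
        """DOY window Mar 1 - May 1 inclusive, computed from the calendar."""
        leap = calendar.isleap(year)
        mar1 = 60 + int(leap)
        may1 = 121 + int(leap)
        return mar1, may1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_doys", "threshold_range", "season_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("window_doys", "threshold_range", "season_bounds"):
            if data[key] is not None:
                data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
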