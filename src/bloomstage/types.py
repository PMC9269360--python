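"""Core domain containers shared across the pipeline.

Units: chlorophyll-a and pheophytin concentrations are numerically identical
in mg/m^3 (satellite) and ug/L (bottle samples); day-of-year (DOY) is 1-based
with Jan 1 = DOY 1 and DOY 366 in leap years.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Stage(str, enum.Enum):
    """Bloom life stage at the time of sampling.

    NB: sampled outside any bloom cycle. EB: at or before the bloom peak.
    PB: after the peak, at or before the bloom end. NAN: the station-year
    failed quality control, so no satellite stage could be assigned.
    """

    NB = "NB"
    EB = "EB"
    PB = "PB"
    NAN = "NAN"

    def __str__(self) -> str:  # keeps CSV output plain
        return self.value


class IceClass(str, enum.Enum):
    HIGH = "HIGH"
    LOW = "LOW"

    def __str__(self) -> str:
        return self.value


@dataclass
class ChlSeries:
    """One station-year of irregular surface chlorophyll-a observations.

    ``doys`` is strictly increasing with no duplicates; ``chl`` is finite and
    non-negative (mg/m^3). ``masked_doys`` records observation days removed by
    the sea-ice mask.
    """

    station_id: str
    year: int
    doys: np.ndarray
    chl: np.ndarray
    masked_doys: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.doys = np.asarray(self.doys, dtype=int)
        self.chl = np.asarray(self.chl, dtype=float)
        if self.doys.shape != self.chl.shape:
            raise ValueError("doys and chl must have the same length")
        if self.doys.size:
            if np.any(np.diff(self.doys) <= 0):
                raise ValueError(
                    f"{self.station_id}/{self.year}: observation DOYs must be "
                    "strictly increasing with no duplicates"
                )
            if np.any(self.doys < 1) or np.any(self.doys > 366):
                raise ValueError("DOY out of range 1..366")
            if np.any(~np.isfinite(self.chl)) or np.any(self.chl < 0):
                raise ValueError("chlorophyll values must be finite and >= 0")

    @property
    def n_obs(self) -> int:
        return int(self.doys.size)


@dataclass
class IceSeries:
    """Daily sea-ice concentration (%) for one station-year.

    ``concentration`` is indexed by DOY-1 over a full calendar year; days with
    no valid retrieval are NaN and listed out of ``coverage``.
    """

    station_id: str
    year: int
    concentration: np.ndarray  # length 365/366, percent, NaN = missing

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        valid = self.concentration[~np.isnan(self.concentration)]
        if valid.size and (valid.min() < 0 or valid.max() > 100):
            raise ValueError("ice concentration must lie in [0, 100]")

    @property
    def coverage(self) -> set[int]:
        return {int(d) + 1 for d in np.flatnonzero(~np.isnan(self.concentration))}

    def at(self, doy: int) -> float:
        """Concentration on a DOY; NaN when missing or out of range."""
        if not 1 <= doy <= self.concentration.size:
            return float("nan")
        return float(self.concentration[doy - 1])


@dataclass
class PigmentSample:
    """One bottle sample of chlorophyll-a and pheophytin (ug/L)."""

    station_id: str
    year: int
    sample_doy: int
    depth_m: float
    chl: float
    pheo: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.depth_m <= 0:
            raise ValueError("depth must be > 0 m (positive downward)")
        if self.chl < 0 or self.pheo < 0:
            raise ValueError("pigment concentrations must be >= 0")
        if self.chl + self.pheo == 0:
            self.below_detection = True


@dataclass
class DailyCurve:
    """Smoothed daily chlorophyll curve on a gap-free DOY grid."""

    station_id: str
    year: int
    doy_grid: np.ndarray  # consecutive integers
    values: np.ndarray

    def __post_init__(self) -> None:
        self.doy_grid = np.asarray(self.doy_grid, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.doy_grid.size and np.any(np.diff(self.doy_grid) != 1):
            raise ValueError("daily grid must be gap-free")

    def contains_doy(self, doy: int) -> bool:
        return self.doy_grid.size > 0 and self.doy_grid[0] <= doy <= self.doy_grid[-1]


@dataclass
class BloomCycle:
    """One detected bloom: start (t1), peak (t2) and end (t3) days.

    ``chl_t2`` is the curve maximum on [t1, t3]; ``amplitude`` = chl_t2 - chl_t1.
    ``truncated_end`` marks cycles whose series ended before the curve
    demonstrably returned to a local minimum.
    """

    t1: int
    t2: int
    t3: int
    chl_t1: float
    chl_t2: float
    chl_t3: float
    truncated_end: bool = False

    @property
    def amplitude(self) -> float:
        return self.chl_t2 - self.chl_t1

    def contains(self, doy: int) -> bool:
        return self.t1 <= doy <= self.t3


@dataclass
class BreakupResult:
    """Sea-ice breakup date for one station-year.

    ``breakup_doy`` is None when no qualifying run exists; ``no_ice_flag`` is
    set when winter ice never reached the breakup threshold at all (open water
    all year), in which case there is no breakup date to report.
    """

    station_id: str
    year: int
    breakup_doy: int | None
    no_ice_flag: bool = False


@dataclass
class ChangePointResult:
    """Single mean-shift fit to a per-station breakup-date sequence."""

    split_index: int | None  # number of years in the first segment
    pre_mean: float
    post_mean: float
    doy_threshold: float


@dataclass
class IceYearClass:
    station_id: str
    year: int
    class_by_breakup: IceClass
    class_by_concentration: IceClass
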