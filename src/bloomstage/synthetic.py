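"""Synthetic study data with the statistical structure the pipeline assumes.

Three generators emulate the pipeline's inputs without any satellite or
cruise downloads:

* chlorophyll series — a baseline plus Gaussian bloom pulses, observed on
  cloud-free days only (i.i.d. missingness by default, ~27 usable
  observations per year) with multiplicative lognormal noise;
* sea-ice series — a winter plateau, a logistic spring decline whose first
  two-day sub-15% run starts exactly at a prescribed breakup day, and
  optional winter open-water episodes;
* pigment profiles — stage-dependent surface pheophytin proportions (low for
  growing blooms, high post-peak) drifting upward with depth, mirroring
  pheopigment accumulation in bottom waters.

Each generator is deterministic given its seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenology import detect_bloom_cycles
from .types import BloomCycle, ChlSeries, DailyCurve, IceSeries, PigmentSample, Stage

__all__ = [
    "BloomSpec",
    "IceSpec",
    "PigmentSpec",
    "gen_chl_series",
    "gen_ice_series",
    "gen_pigment_samples",
    "gen_calibration_dataset",
    "gen_matchup_replica",
    "gen_full_study",
    "CalibrationDataset",
]

# Observation season: the optically retrievable open-water months at these
# latitudes (mid-April to early September). 145 days at 19% daily retention
# gives ~27.5 expected observations per year, the study-scale density.
DEFAULT_SEASON = (106, 250)
DEFAULT_CLOUD_PROB = 0.81
CRUISE_DOYS = (194, 199)  # annual July sampling window


@dataclass
class BloomSpec:
    """Parameters of one synthetic station-year chlorophyll series."""

    baseline: float = 0.3  # mg/m^3
    pulses: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(150.0, 2.0, 12.0)]
    )  # (peak_doy, amplitude mg/m^3, width sigma days)
    noise_cv: float = 0.15
    cloud_prob: float = DEFAULT_CLOUD_PROB
    season: tuple[int, int] = DEFAULT_SEASON
    asymmetry: float = 0.0  # >0 stretches the falling limb of each pulse
    cloud_persistence: float = 0.0  # 0 = i.i.d. missingness
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cloud_prob < 1:
            raise ValueError("cloud_prob must lie in [0, 1)")
        for _, amp, width in self.pulses:
            if amp <= 0 or width <= 0:
                raise ValueError("pulse amplitude and width must be > 0")


def _pulse_curve(spec: BloomSpec, doys: np.ndarray) -> np.ndarray:
    total = np.full(doys.shape, spec.baseline, dtype=float)
    for peak, amp, width in spec.pulses:
        sigma = np.where(doys >= peak, width * (1.0 + spec.asymmetry), width)
        total += amp * np.exp(-0.5 * ((doys - peak) / sigma) ** 2)
    return total


def _cloud_mask(rng: np.random.Generator, n: int, p_cloud: float, persistence: float) -> np.ndarray:
    """True = observed (cloud-free). i.i.d. Bernoulli unless persistence > 0,
    then a symmetric two-state chain with the same stationary cloud rate."""
    if persistence <= 0:
        return rng.random(n) >= p_cloud
    obs = np.empty(n, dtype=bool)
    state = rng.random() >= p_cloud
    for i in range(n):
        obs[i] = state
        stay = persistence
        target = (1 - p_cloud) if state else p_cloud
        flip_p = (1 - stay) * (1 - target)
        if rng.random() < flip_p:
            state = not state
    return obs


def gen_chl_series(
    spec: BloomSpec, year: int, station_id: str = "SYN-1"
) -> tuple[ChlSeries, list[BloomCycle]]:
    """Generate one observed station-year plus its noiseless truth cycles.

    Truth t1/t2/t3 come from running the bloom detector on the noiseless
    daily curve, so "truth" means what a perfectly observed series yields.
    Returns the observed (cloud-thinned, noisy) series and the truth list.
    If every day is clouded out the generator reseeds (logged attempts, max
    5) before giving up.
    """
    lo, hi = spec.season
    doys = np.arange(lo, hi + 1)
    truth = _pulse_curve(spec, doys.astype(float))
    truth_cycles = detect_bloom_cycles(DailyCurve(station_id, year, doys, truth))
    rng = np.random.default_rng(spec.seed)
    for _attempt in range(5):
        keep = _cloud_mask(rng, doys.size, spec.cloud_prob, spec.cloud_persistence)
        if keep.any():
            break
    else:
        raise RuntimeError("all days clouded out in 5 attempts")
    obs_doys = doys[keep]
    values = truth[keep]
    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1 + spec.noise_cv ** 2))
        noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=values.size)
        values = values * noise
    series = ChlSeries(station_id, year, obs_doys, values)
    return series, truth_cycles


@dataclass
class IceSpec:
    """Parameters of one synthetic station-year ice-concentration series."""

    winter_max_pct: float = 95.0
    breakup_doy_true: int = 120
    decline_width: float = 4.0  # logistic width, days
    openwater_episodes: list[tuple[int, int]] = field(default_factory=list)
    no_winter_ice: bool = False  # open water all year (no breakup exists)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.no_winter_ice and not 15 < self.winter_max_pct <= 100:
            raise ValueError("winter_max_pct must lie in (15, 100]")


def gen_ice_series(spec: IceSpec, year: int, station_id: str = "SYN-1") -> IceSeries:
    """Winter plateau, logistic decline timed so the first 2-day run below
    15% starts exactly at ``breakup_doy_true``, near-zero concentrations
    after melt. Open-water episodes punch zero runs into the plateau and may
    not overlap the decline."""
    import calendar as _cal

    n_days = 366 if _cal.isleap(year) else 365
    doys = np.arange(1, n_days + 1, dtype=float)
    if spec.no_winter_ice:
        return IceSeries(station_id, year, np.zeros(n_days))
    m, w, b = spec.winter_max_pct, spec.decline_width, spec.breakup_doy_true
    # centre the logistic so conc(b-1) >= 15 > conc(b)
    d0 = (b - 0.5) - w * math.log(m / 15.0 - 1.0)
    conc = m / (1.0 + np.exp((doys - d0) / w))
    # exact plateau until the logistic has dropped 2% below the winter max,
    # so the last day at maximum concentration sits just before the decline
    plateau_end = d0 - w * math.log(49.0)
    conc[doys <= plateau_end] = m
    conc[conc < 0.05] = 0.0
    for start, length in spec.openwater_episodes:
        end = start + length - 1
        if end >= plateau_end:
            raise ValueError(
                f"open-water episode ({start}, {length}) overlaps the spring decline"
            )
        conc[start - 1:end] = 0.0
    return IceSeries(station_id, year, conc)


@dataclass
class PigmentSpec:
    """Stage-dependent pigment profile generator parameters.

    Surface pheophytin proportions are drawn uniformly from ``eb_range`` for
    growing blooms and ``pb_range`` for post-peak blooms, separated by
    ``true_boundary``; proportions drift upward with depth at
    ``depth_slope`` per metre.
    """

    true_boundary: float = 0.28
    eb_range: tuple[float, float] = (0.10, 0.27)
    pb_range: tuple[float, float] = (0.29, 0.60)
    depths: tuple[float, ...] = (5.0, 15.0, 25.0, 35.0, 50.0)
    depth_slope: float = 0.004  # proportion increase per metre below surface
    surface_total: float = 6.0  # mean combined chl+pheo at 5 m, ug/L
    anchors: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.eb_range[1] < self.true_boundary <= self.pb_range[0]):
            raise ValueError("eb_range must lie below the boundary, pb_range at/above it")


def _profile_from_surface(
    spec: PigmentSpec, p_surface: float, rng: np.random.Generator,
    station: str, year: int, doy: int,
) -> list[PigmentSample]:
    samples = []
    for depth in spec.depths:
        p = min(0.95, p_surface + spec.depth_slope * (depth - spec.depths[0]))
        total = spec.surface_total * math.exp(-(depth - spec.depths[0]) / 60.0)
        total *= rng.lognormal(mean=0.0, sigma=0.2)
        samples.append(PigmentSample(
            station_id=station, year=year, sample_doy=doy, depth_m=depth,
            chl=total * (1 - p), pheo=total * p,
        ))
    return samples


def gen_pigment_samples(
    spec: PigmentSpec,
    stage: Stage | str,
    station: str,
    year: int,
    rng: np.random.Generator | None = None,
    sample_doy: int | None = None,
) -> list[PigmentSample]:
    """One bottle profile whose surface (5 m) proportion reflects ``stage``."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    stage = Stage(str(stage))
    lo, hi = spec.eb_range if stage == Stage.EB else spec.pb_range
    p_surface = float(rng.uniform(lo, hi))
    doy = (sample_doy if sample_doy is not None
           else int(rng.integers(CRUISE_DOYS[0], CRUISE_DOYS[1] + 1)))
    return _profile_from_surface(spec, p_surface, rng, station, year, doy)


@dataclass
class CalibrationDataset:
    """Matched field/satellite dataset for threshold calibration."""

    samples: list[PigmentSample]
    matched: pd.DataFrame  # station_id, year, satellite_stage, surface proportion


def _set_surface_proportion(sample: PigmentSample, p: float) -> None:
    total = sample.chl + sample.pheo
    sample.pheo = total * p
    sample.chl = total * (1 - p)


def gen_calibration_dataset(
    n_station_years: int,
    spec: PigmentSpec | None = None,
    seed: int | None = None,
) -> CalibrationDataset:
    """Matched satellite-stage / pigment-profile table for the threshold scan.

    Satellite labels are assigned in the study's observed class mix (23 EB :
    5 PB); each station-year's profile is generated consistently with its
    label. With ``spec.anchors`` on, one EB surface sample is pinned at
    ``true_boundary - 0.001`` and one PB at exactly ``true_boundary``, which
    makes the boundary's integer percentage the unique perfect threshold.
    """
    if n_station_years < 4:
        raise ValueError("need at least 4 station-years")
    spec = spec or PigmentSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_eb = max(1, round(n_station_years * 23 / 28))
    n_eb = min(n_eb, n_station_years - 1)
    labels = [Stage.EB] * n_eb + [Stage.PB] * (n_station_years - n_eb)
    samples: list[PigmentSample] = []
    rows = []
    first_idx = {Stage.EB: None, Stage.PB: None}
    for i, label in enumerate(labels):
        station = f"ST{i % 13 + 1:02d}"
        year = 2013 + (i % 7)
        profile = gen_pigment_samples(spec, label, station, year, rng=rng)
        if spec.anchors and first_idx[label] is None:
            first_idx[label] = len(samples)
            p_anchor = (spec.true_boundary - 0.001 if label == Stage.EB
                        else spec.true_boundary)
            _set_surface_proportion(profile[0], p_anchor)
        samples.extend(profile)
        surf = profile[0]
        rows.append({
            "station_id": station, "year": year,
            "satellite_stage": str(label),
            "proportion": surf.pheo / (surf.chl + surf.pheo),
        })
    return CalibrationDataset(samples, pd.DataFrame(rows))


def gen_matchup_replica() -> CalibrationDataset:
    """Deterministic dataset whose 28% error matrix is (16, 0, 7, 5).

    23 satellite-EB station-years (16 with surface proportions below 0.28,
    7 with proportions 0.29-0.61, the misclassification pattern observed in
    the study) and 5 satellite-PB station-years all above 0.28.
    """
    props = np.concatenate([
        np.linspace(0.05, 0.26, 16),   # satellite EB, field EB at T=28
        np.linspace(0.29, 0.61, 7),    # satellite EB, field PB (residual pigment)
        np.linspace(0.30, 0.70, 5),    # satellite PB, field PB
    ])
    sat = [Stage.EB] * 23 + [Stage.PB] * 5
    spec = PigmentSpec(anchors=False)
    rng = np.random.default_rng(1)
    samples: list[PigmentSample] = []
    rows = []
    for i, (p, label) in enumerate(zip(props, sat)):
        station = f"ST{i % 13 + 1:02d}"
        year = 2013 + (i % 7)
        profile = _profile_from_surface(spec, float(p), rng, station, year, 196)
        samples.extend(profile)
        rows.append({
            "station_id": station, "year": year,
            "satellite_stage": str(label), "proportion": float(p),
        })
    return CalibrationDataset(samples, pd.DataFrame(rows))


# --- full study preset -----------------------------------------------------

STATIONS_DBO1 = ("SLIP-1", "SLIP-2", "SLIP-3", "SLIP-4", "SLIP-5")
STATIONS_DBO2 = ("BCL-6A", "BCL-6C", "UTBS-1", "UTBS-2", "UTBS-3",
                 "UTBS-4", "UTBS-5", "DBO2.7")
STUDY_YEARS = tuple(range(2013, 2020))
LOW_ICE_YEARS = (2018, 2019)


def gen_full_study(seed: int = 0) -> dict[str, pd.DataFrame]:
    """13 stations x 7 years echoing the study design.

    High-ice years see late breakup (~DOY 135-150) and an early-summer bloom
    whose peak precedes the July cruise (post-peak, pigment-degraded
    samples); low-ice years (2018-2019) see early breakup or no winter ice
    and a later bloom still growing at sampling time (fresh pigment).
    Returns tidy ``chl``, ``ice`` and ``pigments`` tables in the pipeline's
    CSV schemas.
    """
    rng = np.random.default_rng(seed)
    stations = list(STATIONS_DBO1 + STATIONS_DBO2)
    chl_rows, ice_rows, pig_rows = [], [], []
    for station in stations:
        station_offset = float(rng.normal(0.0, 4.0))
        for year in STUDY_YEARS:
            low_ice = year in LOW_ICE_YEARS
            no_ice = year == 2018 and station in ("SLIP-1", "SLIP-2")
            if no_ice:
                ice_spec = IceSpec(no_winter_ice=True)
            else:
                # early breakup in low-ice years puts a long zero-ice run
                # inside the Mar-May window on its own; no episodes needed
                breakup = (95 if low_ice else 140) + station_offset + float(rng.normal(0, 3))
                ice_spec = IceSpec(breakup_doy_true=int(round(breakup)))
            ice = gen_ice_series(ice_spec, year, station)
            for d in range(1, ice.concentration.size + 1):
                ice_rows.append({"station_id": station, "year": year,
                                 "doy": d, "ice_pct": round(ice.at(d), 2)})
            # bloom timing: high-ice years peak around the July cruise (many
            # already post-peak); low-ice years bloom later and are still
            # rising when sampled
            peak = float(rng.normal(208, 8) if low_ice else rng.normal(185, 12))
            bloom_spec = BloomSpec(
                pulses=[(peak, float(rng.uniform(1.2, 2.5)), float(rng.uniform(9, 14)))],
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            series, _ = gen_chl_series(bloom_spec, year, station)
            for d, c in zip(series.doys, series.chl):
                chl_rows.append({"station_id": station, "year": year,
                                 "doy": int(d), "chl_mg_m3": round(float(c), 4)})
            # field stage follows the true peak; a quarter of growing blooms
            # still carry high pheophytin left from a recently ended prior
            # bloom, the mismatch pattern the satellite comparison sees
            sample_doy = int(rng.integers(CRUISE_DOYS[0], CRUISE_DOYS[1] + 1))
            stage = Stage.EB if sample_doy <= peak else Stage.PB
            pigment_stage = stage
            if stage == Stage.EB and rng.random() < 0.25:
                pigment_stage = Stage.PB
            pig_spec = PigmentSpec(anchors=False)
            for s in gen_pigment_samples(pig_spec, pigment_stage, station, year,
                                         rng=rng, sample_doy=sample_doy):
                pig_rows.append({
                    "station_id": station, "year": year, "doy": s.sample_doy,
                    "depth_m": s.depth_m, "chl_ug_L": round(s.chl, 4),
                    "pheo_ug_L": round(s.pheo, 4),
                })
    return {
        "chl": pd.DataFrame(chl_rows),
        "ice": pd.DataFrame(ice_rows),
        "pigments": pd.DataFrame(pig_rows),
    }
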