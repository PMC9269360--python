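"""Satellite chlorophyll phenology: ice masking, QC, smoothing, bloom
detection and stage classification.

The workflow for one station-year mirrors the staging protocol: drop
observations taken under more than 15% sea-ice concentration, apply quality
control (enough observations, no long gaps, coverage of the mid-summer
window), smooth the retained points with a tricube locally weighted linear
fit, interpolate linearly onto a daily grid, segment the daily curve into
bloom cycles that rise at least 0.5 mg/m^3 from their starting minimum, and
classify a sampling day as No Bloom / Early Bloom / Post Bloom against the
cycle boundaries:

    NB: doy < t1 or doy > t3
    EB: t1 <= doy <= t2
    PB: t2 <  doy <= t3
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import RunConfig
from .types import BloomCycle, ChlSeries, DailyCurve, IceSeries, Stage

__all__ = [
    "mask_ice_days",
    "qc_series",
    "QCResult",
    "fit_phenology_curve",
    "detect_bloom_cycles",
    "classify_stage",
    "stage_series",
]


class PairingError(ValueError):
    """Chlorophyll and ice series do not belong to the same station-year."""


class OutOfCoverageError(ValueError):
    """Sampling DOY lies outside the daily curve's grid."""


def mask_ice_days(series: ChlSeries, ice: IceSeries, ice_mask_pct: float = 15.0) -> ChlSeries:
    """Remove observations on days with ice concentration strictly above
    ``ice_mask_pct``; days with missing ice data are retained."""
    if (series.station_id, series.year) != (ice.station_id, ice.year):
        raise PairingError(
            f"cannot pair chlorophyll {series.station_id}/{series.year} "
            f"with ice {ice.station_id}/{ice.year}"
        )
    conc = np.array([ice.at(int(d)) for d in series.doys])
    drop = conc > ice_mask_pct  # NaN compares False -> retained
    masked = set(series.masked_doys) | {int(d) for d in series.doys[drop]}
    return ChlSeries(
        station_id=series.station_id,
        year=series.year,
        doys=series.doys[~drop],
        chl=series.chl[~drop],
        masked_doys=masked,
    )


@dataclass
class QCResult:
    passed: bool
    failing_rule: str | None = None
    detail: str | None = None


def qc_series(series: ChlSeries, config: RunConfig | None = None) -> QCResult:
    """Quality-control one masked station-year.

    Fails on the first violated rule among: fewer than ``min_obs_per_year``
    observations; any gap between consecutive observations (and, when
    ``season_bounds`` is set, between the bounds and the terminal
    observations) longer than ``max_gap_days``; fewer than
    ``min_obs_in_window`` observations inside the mid-summer window.
    """
    cfg = config or RunConfig()
    if series.n_obs < cfg.min_obs_per_year:
        return QCResult(False, "min_observations",
                        f"{series.n_obs} < {cfg.min_obs_per_year} observations")
    doys = series.doys
    gaps = np.diff(doys)
    if gaps.size and gaps.max() > cfg.max_gap_days:
        i = int(np.argmax(gaps))
        return QCResult(False, "max_gap",
                        f"{gaps.max()}-day gap between DOY {doys[i]} and {doys[i + 1]}")
    if cfg.season_bounds is not None:
        lo, hi = cfg.season_bounds
        if doys[0] - lo > cfg.max_gap_days or hi - doys[-1] > cfg.max_gap_days:
            return QCResult(False, "max_gap",
                            "gap between seasonal bound and terminal observation "
                            f"exceeds {cfg.max_gap_days} days")
    w_lo, w_hi = cfg.window_doys
    in_window = int(np.count_nonzero((doys >= w_lo) & (doys <= w_hi)))
    if in_window < cfg.min_obs_in_window:
        return QCResult(False, "window_coverage",
                        f"{in_window} < {cfg.min_obs_in_window} observations "
                        f"in DOY {w_lo}-{w_hi}")
    return QCResult(True)


def fit_phenology_curve(
    series: ChlSeries,
    span: float | None = None,
    min_points: int = 7,
    robust_iters: int = 0,
) -> DailyCurve:
    """Smooth the series and interpolate onto a daily grid.

    A tricube-weighted local linear regression (LOWESS) is evaluated at each
    observation DOY; a daily curve between the first and last observation is
    then produced by linear interpolation between the smoothed points. The
    curve never extrapolates beyond the observed DOY range.

    ``span`` is the fraction of points in each local fit; the default is
    max(``min_points``, 30% of n) points. A span resolving to fewer than 3
    points per local fit is rejected.
    """
    n = series.n_obs
    if n == 0:
        raise ValueError("cannot fit an empty series")
    if span is None:
        frac = min(1.0, max(min_points, math.ceil(0.30 * n)) / n)
    else:
        frac = float(span)
    if frac * n < 3:
        raise ValueError(f"span {frac:.3f} yields fewer than 3 points per local fit")
    x = series.doys.astype(float)
    smoothed = lowess(series.chl, x, frac=frac, it=robust_iters, return_sorted=False)
    grid = np.arange(series.doys[0], series.doys[-1] + 1)
    values = np.interp(grid, x, smoothed)
    return DailyCurve(series.station_id, series.year, grid, values)


def _plateau_runs(values: np.ndarray) -> list[tuple[int, float]]:
    """Compress consecutive equal values; return (first_index, value) runs."""
    runs: list[tuple[int, float]] = []
    for i, v in enumerate(values):
        if not runs or runs[-1][1] != v:
            runs.append((i, float(v)))
    return runs


def _segment_boundaries(values: np.ndarray) -> tuple[list[int], bool]:
    """Indices of segmentation minima (plateaus collapsed to their first day).

    Returns the boundary indices (always starting at 0 and ending at the
    final boundary) and whether the final boundary is a *confirmed* minimum
    (the curve levelled off or rose after it) rather than the raw series end.
    """
    n = values.size
    runs = _plateau_runs(values)
    bounds = [0]
    for k in range(1, len(runs) - 1):
        prev_v, v, next_v = runs[k - 1][1], runs[k][1], runs[k + 1][1]
        if prev_v > v < next_v:
            bounds.append(runs[k][0])
    # final boundary: a descending terminal run counts as the minimum at its
    # first day; it is confirmed only if the plateau lasts beyond one day
    confirmed_end = False
    if len(runs) >= 2 and runs[-1][1] < runs[-2][1]:
        end = runs[-1][0]
        confirmed_end = end < n - 1  # plateau of >=2 days
    else:
        end = n - 1
    if end != bounds[-1]:
        bounds.append(end)
    return bounds, confirmed_end


def detect_bloom_cycles(curve: DailyCurve, bloom_rise_min: float = 0.5) -> list[BloomCycle]:
    """Segment the daily curve at strict local minima and keep cycles rising
    at least ``bloom_rise_min`` above their starting minimum.

    Plateaus collapse to their first day (so a maximal plateau peaks at its
    earliest day, and t2 is deterministic). A segment whose rise stays below
    the threshold is merged into the preceding qualifying bloom when the
    intervening minimum remains above that bloom's starting value (a
    continuation of the larger cycle); otherwise it contributes no cycle.
    A cycle whose end is the raw end of the series is flagged truncated.
    """
    v = curve.values
    n = v.size
    if n == 0:
        return []
    bounds, confirmed_end = _segment_boundaries(v)
    segments = list(zip(bounds[:-1], bounds[1:]))
    if bounds[-1] < n - 1:
        # trailing descending plateau: not a segment of its own
        pass

    def seg_qualifies(a: int, b: int) -> bool:
        return float(v[a:b + 1].max()) - float(v[a]) >= bloom_rise_min

    merged: list[tuple[int, int]] = []  # (t1_idx, t3_idx)
    current: tuple[int, int] | None = None
    for a, b in segments:
        if seg_qualifies(a, b):
            if current is not None:
                merged.append(current)
            current = (a, b)
        elif current is not None and v[a] > v[current[0]]:
            current = (current[0], b)  # continuation of the open bloom
        else:
            if current is not None:
                merged.append(current)
            current = None
    if current is not None:
        merged.append(current)

    cycles: list[BloomCycle] = []
    for a, b in merged:
        seg = v[a:b + 1]
        t2_idx = a + int(np.argmax(seg))  # earliest day of a maximal plateau
        truncated = (b == n - 1) and not confirmed_end
        cycles.append(BloomCycle(
            t1=int(curve.doy_grid[a]),
            t2=int(curve.doy_grid[t2_idx]),
            t3=int(curve.doy_grid[b]),
            chl_t1=float(v[a]),
            chl_t2=float(v[t2_idx]),
            chl_t3=float(v[b]),
            truncated_end=truncated,
        ))
    return cycles


def classify_stage(
    cycles: list[BloomCycle],
    sample_doy: int,
    curve: DailyCurve | None = None,
) -> Stage:
    """Stage at ``sample_doy``: EB on [t1, t2], PB on (t2, t3], NB outside
    every cycle. When two cycles share a boundary day the earlier cycle wins.

    If ``curve`` is given, a sampling day outside its grid raises
    :class:`OutOfCoverageError` (distinct from NB: the curve says nothing
    there).
    """
    if curve is not None and not curve.contains_doy(sample_doy):
        raise OutOfCoverageError(
            f"DOY {sample_doy} outside curve grid "
            f"[{curve.doy_grid[0]}, {curve.doy_grid[-1]}]"
        )
    for c in cycles:
        if c.contains(sample_doy):
            return Stage.EB if sample_doy <= c.t2 else Stage.PB
    return Stage.NB


def stage_series(
    series: ChlSeries,
    ice: IceSeries | None,
    sample_doy: int,
    config: RunConfig | None = None,
) -> tuple[Stage, QCResult, list[BloomCycle]]:
    """Full per-station-year staging: mask, QC, smooth, detect, classify.

    Returns NAN (with the failing QC rule) when the series fails quality
    control or the sampling day falls outside the smoothed curve's coverage.
    """
    cfg = config or RunConfig()
    if ice is not None:
        series = mask_ice_days(series, ice, cfg.ice_mask_pct)
    qc = qc_series(series, cfg)
    if not qc.passed:
        return Stage.NAN, qc, []
    curve = fit_phenology_curve(
        series, min_points=cfg.lowess_min_points, robust_iters=cfg.lowess_robust_iters
    )
    cycles = detect_bloom_cycles(curve, cfg.bloom_rise_min)
    try:
        stage = classify_stage(cycles, sample_doy, curve)
    except OutOfCoverageError:
        return Stage.NAN, QCResult(False, "out_of_coverage",
                                   f"sampling DOY {sample_doy} outside coverage"), cycles
    return stage, qc, cycles
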