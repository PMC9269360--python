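"""Sea-ice year classification: breakup dates, single changepoint, and the
spring open-water rule.

Two independent schemes label each station-year HIGH or LOW ice:

* breakup scheme — the breakup date (first day of the first 2-day run below
  15% concentration after the winter maximum) is compared against a
  per-station DOY threshold derived from an at-most-one-change (AMOC) mean
  shift fitted to that station's multi-year breakup sequence;
* concentration scheme — a year is LOW when the Mar 1 - May 1 window contains
  a run of more than five consecutive zero-concentration days; HIGH is the
  default.

Station-years where winter ice never formed have no breakup date and are
treated as the low-ice extreme under both schemes.
"""
from __future__ import annotations

import math

import numpy as np

from .config import RunConfig
from .types import BreakupResult, ChangePointResult, IceClass, IceSeries

__all__ = [
    "breakup_doy",
    "concentration_ice_class",
    "amoc_changepoint",
    "breakup_ice_class",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


def breakup_doy(ice: IceSeries, breakup_pct: float = 15.0, run_days: int = 2) -> BreakupResult:
    """First day of the earliest ``run_days``-long run of valid days strictly
    below ``breakup_pct``, searched after the (last day of the) winter
    maximum so early-winter open water cannot register as breakup.

    If concentration never reaches ``breakup_pct`` at any time of the year,
    winter ice never formed: ``no_ice_flag`` is set and no date is reported.
    Missing days break candidate runs.
    """
    conc = ice.concentration
    valid = ~np.isnan(conc)
    if not valid.any():
        raise InsufficientDataError(f"{ice.station_id}/{ice.year}: no valid ice data")
    vmax = np.nanmax(conc)
    if vmax < breakup_pct:
        return BreakupResult(ice.station_id, ice.year, None, no_ice_flag=True)
    start = int(np.flatnonzero(valid & (conc == vmax))[-1])  # last day at maximum
    below = valid & (conc < breakup_pct)
    run = 0
    for i in range(start, conc.size):
        run = run + 1 if below[i] else 0
        if run == run_days:
            return BreakupResult(ice.station_id, ice.year, i - run_days + 2, False)
    return BreakupResult(ice.station_id, ice.year, None, no_ice_flag=False)


def concentration_ice_class(
    ice: IceSeries,
    openwater_window: tuple[int, int] | None = None,
    run_days_exclusive: int = 5,
) -> IceClass:
    """LOW iff the Mar 1 - May 1 window contains a run of strictly more than
    ``run_days_exclusive`` consecutive zero-concentration days (zero meaning
    rounding to 0 at integer-percent precision); HIGH is the default.

    Missing days inside the window break runs.
    """
    lo, hi = openwater_window or RunConfig.openwater_window(ice.year)
    conc = ice.concentration[lo - 1:hi]
    run = 0
    for v in conc:
        if not math.isnan(v) and round(v) == 0:
            run += 1
            if run > run_days_exclusive:
                return IceClass.LOW
        else:
            run = 0
    return IceClass.HIGH


def amoc_changepoint(
    breakup_doys,
    min_segment: int = 2,
    penalty_scale: float = 2.0,
) -> ChangePointResult:
    """At-most-one-change mean shift on a per-station breakup-date sequence.

    Exhaustively scans every split position (segments of at least
    ``min_segment`` years) for the split minimizing the total within-segment
    sum of squared deviations. The split is accepted only when the SSE
    reduction over the no-change model exceeds ``penalty_scale * ln(n)``
    times the residual variance of the two-segment fit. The returned DOY
    threshold is the midpoint of the segment means (the overall mean when no
    split is accepted).
    """
    x = np.asarray([d for d in breakup_doys if d is not None], dtype=float)
    n = x.size
    if n < 2 * min_segment:
        raise InsufficientDataError(
            f"need >= {2 * min_segment} breakup dates, got {n}"
        )
    sse_null = float(((x - x.mean()) ** 2).sum())
    best_k, best_sse = None, np.inf
    for k in range(min_segment, n - min_segment + 1):
        a, b = x[:k], x[k:]
        sse = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
        if sse < best_sse:
            best_k, best_sse = k, sse
    assert best_k is not None
    var = best_sse / max(n - 2, 1)
    penalty = penalty_scale * math.log(n) * var
    if sse_null - best_sse > penalty:
        pre, post = float(x[:best_k].mean()), float(x[best_k:].mean())
        return ChangePointResult(best_k, pre, post, (pre + post) / 2.0)
    mean = float(x.mean())
    return ChangePointResult(None, mean, mean, mean)


def breakup_ice_class(result: BreakupResult, doy_threshold: float) -> IceClass:
    """LOW when breakup preceded the station's DOY threshold or winter ice
    never formed; HIGH otherwise (breakup at or after the threshold)."""
    if result.no_ice_flag:
        return IceClass.LOW
    if result.breakup_doy is None:
        return IceClass.HIGH  # ice never broke up: the high-ice extreme
    return IceClass.LOW if result.breakup_doy < doy_threshold else IceClass.HIGH
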