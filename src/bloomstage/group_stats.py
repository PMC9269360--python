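"""Depth integration of pigment profiles and high- vs low-ice group
comparison with Welch's unequal-variance t-test."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import UndefinedProportionError, pheophytin_proportion
from .types import IceClass, PigmentSample

__all__ = [
    "depth_integrated_proportion",
    "IntegratedProportion",
    "welch_t",
    "welch_t_from_summary",
    "GroupComparison",
    "summarize_ice_groups",
    "InsufficientGroupError",
]


class InsufficientGroupError(ValueError):
    pass


@dataclass
class IntegratedProportion:
    station_id: str
    year: int
    int_chl: float   # mg/m^2
    int_pheo: float  # mg/m^2
    proportion: float


def depth_integrated_proportion(samples: list[PigmentSample]) -> IntegratedProportion:
    """Trapezoidal depth integrals of chlorophyll and pheophytin over the
    sampled depths; the proportion is the ratio of the pheophytin integral to
    the summed integrals. A single-depth profile degenerates to the pointwise
    proportion. No extrapolation beyond the shallowest/deepest sample.
    """
    if not samples:
        raise ValueError("empty profile")
    keys = {(s.station_id, s.year) for s in samples}
    if len(keys) > 1:
        raise ValueError(f"profile mixes station-years: {sorted(keys)}")
    ordered = sorted(samples, key=lambda s: s.depth_m)
    depths = np.array([s.depth_m for s in ordered])
    if np.any(np.diff(depths) == 0):
        raise ValueError("duplicate sampling depths in profile")
    chl = np.array([s.chl for s in ordered])
    pheo = np.array([s.pheo for s in ordered])
    station, year = ordered[0].station_id, ordered[0].year
    if depths.size == 1:
        p = pheophytin_proportion(float(chl[0]), float(pheo[0]))
        return IntegratedProportion(station, year, float(chl[0]), float(pheo[0]), p)
    int_chl = float(np.trapezoid(chl, depths))
    int_pheo = float(np.trapezoid(pheo, depths))
    if int_chl + int_pheo == 0:
        raise UndefinedProportionError("both pigment integrals are zero")
    return IntegratedProportion(station, year, int_chl, int_pheo,
                                int_pheo / (int_chl + int_pheo))


def _welch_df(v1: float, n1: int, v2: float, n2: int) -> float:
    num = (v1 / n1 + v2 / n2) ** 2
    den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    return num / den


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test on raw values.

    Returns (t, df, p) with t = (mean_a - mean_b)/sqrt(s_a^2/n_a + s_b^2/n_b),
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientGroupError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise InsufficientGroupError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), _welch_df(va, a.size, vb, b.size), float(res.pvalue)


def welch_t_from_summary(
    n1: int, m1: float, s1: float, n2: int, m2: float, s2: float
) -> tuple[float, float, float]:
    """Welch's t-test from group summaries (n, mean, sample SD); same
    formulas as :func:`welch_t`, usable on published summary tables."""
    if n1 < 2 or n2 < 2:
        raise InsufficientGroupError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if s1 == 0 and s2 == 0:
        raise InsufficientGroupError("both groups have zero variance")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    return float(res.statistic), _welch_df(s1 ** 2, n1, s2 ** 2, n2), float(res.pvalue)


@dataclass
class GroupComparison:
    """One high-vs-low ice comparison cell (a level x scheme combination)."""

    level: str   # surface | depth_integrated
    scheme: str  # breakup | concentration
    stats_low: dict
    stats_high: dict
    t: float | None
    df: float | None
    p: float | None
    significant: bool | None
    computable: bool = True
    reason: str | None = None


def _describe(values: np.ndarray) -> dict:
    return {
        "n": int(values.size),
        "mean": float(values.mean()) if values.size else None,
        "sd": float(values.std(ddof=1)) if values.size > 1 else None,
        "min": float(values.min()) if values.size else None,
        "max": float(values.max()) if values.size else None,
    }


def summarize_ice_groups(
    proportions: pd.DataFrame,
    scheme: str,
    level: str,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare pheophytin proportions between LOW and HIGH ice station-years.

    ``proportions`` needs columns ``proportion`` and ``ice_class``
    (HIGH/LOW). A bin with fewer than two station-years makes the comparison
    not-computable (summaries are still reported).
    """
    low = proportions.loc[proportions["ice_class"].astype(str) == "LOW", "proportion"].to_numpy(float)
    high = proportions.loc[proportions["ice_class"].astype(str) == "HIGH", "proportion"].to_numpy(float)
    out = GroupComparison(level, scheme, _describe(low), _describe(high),
                          None, None, None, None)
    try:
        t, df, p = welch_t(low, high)
    except InsufficientGroupError as exc:
        out.computable = False
        out.reason = str(exc)
        return out
    out.t, out.df, out.p = t, df, p
    out.significant = p < alpha
    return out
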