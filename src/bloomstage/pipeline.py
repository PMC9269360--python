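"""End-to-end orchestration: threshold calibration and the high- vs low-ice
comparison, from the three raw input tables to the published result layouts."""
from __future__ import annotations

import logging
from collections import defaultdict

import pandas as pd

from . import group_stats, phenology, seaice
from .calibration import (
    EmptyCalibrationError,
    ThresholdScan,
    accuracy_metrics,
    build_error_matrix,
    classify_field_stage,
    pheophytin_proportion,
    scan_thresholds,
)
from .config import RunConfig
from .io import SURFACE_DEPTH_M
from .types import ChlSeries, IceClass, IceSeries, PigmentSample, Stage

log = logging.getLogger("bloomstage")

__all__ = ["run_calibration", "run_ice_comparison", "stage_table", "ice_year_table"]


def _surface_samples(samples: list[PigmentSample]) -> dict[tuple[str, int], PigmentSample]:
    out: dict[tuple[str, int], PigmentSample] = {}
    for s in samples:
        if s.depth_m == SURFACE_DEPTH_M and not s.below_detection:
            out.setdefault((s.station_id, s.year), s)
    return out


def stage_table(
    chl_series: dict[tuple[str, int], ChlSeries],
    ice_series: dict[tuple[str, int], IceSeries],
    samples: list[PigmentSample],
    config: RunConfig | None = None,
    threshold_pct: int | None = None,
) -> pd.DataFrame:
    """Per-station-year satellite stage and field proportion.

    Satellite staging runs the full phenology chain at the station-year's
    sampling DOY; the field stage column is filled only when
    ``threshold_pct`` is given. Station-years excluded by QC are logged with
    the failing rule and labelled NAN.
    """
    cfg = config or RunConfig()
    surface = _surface_samples(samples)
    rows = []
    for (station, year), series in sorted(chl_series.items()):
        ice = ice_series.get((station, year))
        surf = surface.get((station, year))
        sample_doy = surf.sample_doy if surf else (cfg.window_doys[0] + cfg.window_doys[1]) // 2
        stage, qc, cycles = phenology.stage_series(series, ice, sample_doy, cfg)
        if not qc.passed:
            log.info("excluded %s/%s: rule=%s (%s)", station, year, qc.failing_rule, qc.detail)
        prop = pheophytin_proportion(surf.chl, surf.pheo) if surf else None
        field_stage = (str(classify_field_stage(prop, threshold_pct))
                       if (prop is not None and threshold_pct is not None) else None)
        rows.append({
            "station_id": station, "year": year,
            "satellite_stage": str(stage),
            "field_proportion": prop,
            "field_stage": field_stage,
            "qc_rule": qc.failing_rule,
            "n_cycles": len(cycles),
        })
    return pd.DataFrame(rows)


def cycles_table(
    chl_series: dict[tuple[str, int], ChlSeries],
    ice_series: dict[tuple[str, int], IceSeries],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-bloom table (t1, t2, t3 and their chlorophyll values)."""
    cfg = config or RunConfig()
    rows = []
    for (station, year), series in sorted(chl_series.items()):
        ice = ice_series.get((station, year))
        if ice is not None:
            series = phenology.mask_ice_days(series, ice, cfg.ice_mask_pct)
        if not phenology.qc_series(series, cfg).passed:
            continue
        curve = phenology.fit_phenology_curve(
            series, min_points=cfg.lowess_min_points,
            robust_iters=cfg.lowess_robust_iters)
        for c in phenology.detect_bloom_cycles(curve, cfg.bloom_rise_min):
            rows.append({
                "station_id": station, "year": year,
                "t1": c.t1, "t2": c.t2, "t3": c.t3,
                "chl_t1": c.chl_t1, "chl_t2": c.chl_t2, "chl_t3": c.chl_t3,
                "truncated_end": c.truncated_end,
            })
    return pd.DataFrame(rows, columns=["station_id", "year", "t1", "t2", "t3",
                                       "chl_t1", "chl_t2", "chl_t3", "truncated_end"])


def run_calibration(
    chl_series: dict[tuple[str, int], ChlSeries],
    ice_series: dict[tuple[str, int], IceSeries],
    samples: list[PigmentSample],
    config: RunConfig | None = None,
) -> dict:
    """Calibrate the pheophytin threshold against satellite stages.

    Stages every station-year, pairs satellite EB/PB labels with surface
    pheophytin proportions (No Bloom and NAN station-years are excluded),
    scans all integer thresholds and reports the scan table, the selected
    threshold, its error matrix and accuracy metrics, plus the stage table
    with field stages at the selected threshold.
    """
    cfg = config or RunConfig()
    stages = stage_table(chl_series, ice_series, samples, cfg)
    usable = stages[
        stages["satellite_stage"].isin(["EB", "PB"]) & stages["field_proportion"].notna()
    ]
    if usable.empty:
        raise EmptyCalibrationError(
            "no station-years with both a satellite EB/PB label and a surface sample"
        )
    scan = scan_thresholds(
        usable["field_proportion"], usable["satellite_stage"], cfg.threshold_range
    )
    selected = scan.selected
    field = [classify_field_stage(p, selected) for p in usable["field_proportion"]]
    matrix = build_error_matrix(field, list(usable["satellite_stage"]))
    stages = stage_table(chl_series, ice_series, samples, cfg, threshold_pct=selected)
    return {
        "stages": stages,
        "scan": scan,
        "selected_threshold": selected,
        "error_matrix": matrix,
        "metrics": accuracy_metrics(matrix),
        "n_matched": int(len(usable)),
    }


def ice_year_table(
    ice_series: dict[tuple[str, int], IceSeries],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Breakup dates, per-station changepoint thresholds and both HIGH/LOW
    classifications for every station-year."""
    cfg = config or RunConfig()
    by_station: dict[str, list] = defaultdict(list)
    results = {}
    for (station, year), ice in sorted(ice_series.items()):
        res = seaice.breakup_doy(ice, cfg.breakup_pct, cfg.breakup_run_days)
        results[(station, year)] = res
        by_station[station].append(res)
    thresholds: dict[str, float | None] = {}
    for station, res_list in by_station.items():
        usable = [r.breakup_doy for r in res_list if not r.no_ice_flag and r.breakup_doy]
        try:
            cp = seaice.amoc_changepoint(usable, penalty_scale=cfg.amoc_penalty_scale)
            thresholds[station] = cp.doy_threshold
        except seaice.InsufficientDataError:
            thresholds[station] = None
            log.info("station %s: too few breakup dates for a changepoint", station)
    rows = []
    for (station, year), res in sorted(results.items()):
        thr = thresholds[station]
        cls_b = (seaice.breakup_ice_class(res, thr) if thr is not None
                 else (IceClass.LOW if res.no_ice_flag else IceClass.HIGH))
        cls_c = seaice.concentration_ice_class(
            ice_series[(station, year)],
            run_days_exclusive=cfg.openwater_run_days_exclusive)
        rows.append({
            "station_id": station, "year": year,
            "breakup_doy": res.breakup_doy, "no_ice_flag": res.no_ice_flag,
            "doy_threshold": thr,
            "class_by_breakup": str(cls_b), "class_by_concentration": str(cls_c),
        })
    return pd.DataFrame(rows)


def run_ice_comparison(
    samples: list[PigmentSample],
    ice_series: dict[tuple[str, int], IceSeries],
    config: RunConfig | None = None,
) -> dict:
    """Four-way pheophytin-proportion comparison (surface and depth-
    integrated, by breakup-date and concentration binning) between high- and
    low-ice station-years, with Welch's t-test per cell."""
    cfg = config or RunConfig()
    ice_years = ice_year_table(ice_series, cfg)
    key = ice_years.set_index(["station_id", "year"])

    profiles: dict[tuple[str, int], list[PigmentSample]] = defaultdict(list)
    for s in samples:
        profiles[(s.station_id, s.year)].append(s)

    rows = []
    for (station, year), profile in sorted(profiles.items()):
        if (station, year) not in key.index:
            log.info("no ice record for %s/%s; skipped", station, year)
            continue
        surf = next((s for s in sorted(profile, key=lambda s: s.depth_m)
                     if s.depth_m == SURFACE_DEPTH_M and not s.below_detection), None)
        entry = {
            "station_id": station, "year": year,
            "class_by_breakup": key.loc[(station, year), "class_by_breakup"],
            "class_by_concentration": key.loc[(station, year), "class_by_concentration"],
            "surface": pheophytin_proportion(surf.chl, surf.pheo) if surf else None,
        }
        try:
            entry["depth_integrated"] = group_stats.depth_integrated_proportion(profile).proportion
        except ValueError:
            entry["depth_integrated"] = None
        rows.append(entry)
    props = pd.DataFrame(rows)

    comparisons = []
    for level in ("depth_integrated", "surface"):
        for scheme in ("concentration", "breakup"):
            sub = props[["station_id", "year", level, f"class_by_{scheme}"]].dropna()
            sub = sub.rename(columns={level: "proportion", f"class_by_{scheme}": "ice_class"})
            comparisons.append(
                group_stats.summarize_ice_groups(sub, scheme, level, cfg.alpha))
    return {"proportions": props, "comparisons": comparisons,
            "table": comparison_frame(comparisons)}


def comparison_frame(comparisons) -> pd.DataFrame:
    """Tidy layout of the four comparisons: one row per (level, scheme,
    ice class) with group summaries and the shared test statistics."""
    rows = []
    for c in comparisons:
        for cls, st in (("LOW", c.stats_low), ("HIGH", c.stats_high)):
            rows.append({
                "level": c.level, "scheme": c.scheme, "ice_class": cls,
                "n": st["n"], "mean": st["mean"], "sd": st["sd"],
                "min": st["min"], "max": st["max"],
                "t": c.t, "df": c.df, "p": c.p,
                "significant": c.significant, "computable": c.computable,
            })
    return pd.DataFrame(rows)
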