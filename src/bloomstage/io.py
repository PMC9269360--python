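"""CSV readers and writers for the three pipeline inputs and result tables.

All external tables are UTF-8, comma-delimited CSV with a mandatory header
row. Input schemas:

* chlorophyll — ``station_id,year,doy,chl_mg_m3``
* sea ice     — ``station_id,year,doy,ice_pct``
* pigments    — ``station_id,year,doy,depth_m,chl_ug_L,pheo_ug_L``
"""
from __future__ import annotations

import calendar
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ChlSeries, IceSeries, PigmentSample

__all__ = [
    "read_chl_series",
    "read_ice_series",
    "read_pigment_samples",
    "write_table",
    "FormatError",
    "RowError",
    "SURFACE_DEPTH_M",
]

SURFACE_DEPTH_M = 5.0  # the study's surface-sample convention


class FormatError(ValueError):
    """The file does not match the expected schema."""


class RowError(ValueError):
    """A specific row holds an invalid value; the message names its line."""


def _load(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _check_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise RowError(f"{path} line {line}: non-numeric value in '{col}'")
    return out


def read_chl_series(path: str | Path) -> dict[tuple[str, int], ChlSeries]:
    """One :class:`ChlSeries` per (station, year), observations sorted by DOY.

    Duplicate (station, year, doy) rows are rejected.
    """
    df = _load(path, ["station_id", "year", "doy", "chl_mg_m3"])
    df["chl_mg_m3"] = _check_numeric(df, "chl_mg_m3", path)
    dup = df.duplicated(subset=["station_id", "year", "doy"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise RowError(f"{path} line {line}: duplicate (station, year, doy) row")
    out: dict[tuple[str, int], ChlSeries] = {}
    for (station, year), g in df.groupby(["station_id", "year"], sort=True):
        g = g.sort_values("doy")
        out[(str(station), int(year))] = ChlSeries(
            str(station), int(year),
            g["doy"].to_numpy(int), g["chl_mg_m3"].to_numpy(float),
        )
    return out


def read_ice_series(path: str | Path) -> dict[tuple[str, int], IceSeries]:
    """Daily ice vectors per (station, year); DOYs absent from the file are
    recorded as missing (NaN), never as zero."""
    df = _load(path, ["station_id", "year", "doy", "ice_pct"])
    df["ice_pct"] = _check_numeric(df, "ice_pct", path)
    bad = (df["ice_pct"] < 0) | (df["ice_pct"] > 100)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise RowError(f"{path} line {line}: ice_pct outside [0, 100]")
    out: dict[tuple[str, int], IceSeries] = {}
    for (station, year), g in df.groupby(["station_id", "year"], sort=True):
        year = int(year)
        n_days = 366 if calendar.isleap(year) else 365
        conc = np.full(n_days, np.nan)
        doys = g["doy"].to_numpy(int)
        if doys.min() < 1 or doys.max() > n_days:
            raise RowError(f"{path}: DOY outside 1..{n_days} for {station}/{year}")
        conc[doys - 1] = g["ice_pct"].to_numpy(float)
        out[(str(station), year)] = IceSeries(str(station), year, conc)
    return out


def read_pigment_samples(path: str | Path) -> list[PigmentSample]:
    """One :class:`PigmentSample` per row; chl=pheo=0 rows are accepted but
    flagged below-detection. Surface samples are those at 5 m depth."""
    df = _load(path, ["station_id", "year", "doy", "depth_m", "chl_ug_L", "pheo_ug_L"])
    for col in ("depth_m", "chl_ug_L", "pheo_ug_L"):
        df[col] = _check_numeric(df, col, path)
    samples = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        if row["depth_m"] <= 0:
            raise RowError(f"{path} line {line}: depth must be > 0 m")
        if row["chl_ug_L"] < 0 or row["pheo_ug_L"] < 0:
            raise RowError(f"{path} line {line}: negative pigment concentration")
        samples.append(PigmentSample(
            station_id=str(row["station_id"]), year=int(row["year"]),
            sample_doy=int(row["doy"]), depth_m=float(row["depth_m"]),
            chl=float(row["chl_ug_L"]), pheo=float(row["pheo_ug_L"]),
        ))
    return samples


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as UTF-8 CSV (header row, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
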