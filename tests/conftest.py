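import numpy as np
import pytest

from bloomstage.types import ChlSeries, DailyCurve, IceSeries, PigmentSample

# Published count table: field rows x satellite columns, classes (EB, PB).
MATCHUP_COUNTS = np.array([[16, 0], [7, 5]])


@pytest.fixture
def matchup_labels():
    """The 28 matched field/satellite label pairs behind the count table."""
    pairs = ([("EB", "EB")] * 16 + [("PB", "EB")] * 7 + [("PB", "PB")] * 5)
    field, sat = zip(*pairs)
    return list(field), list(sat)


def make_curve(values, start_doy=100, station="ST1", year=2015) -> DailyCurve:
    values = np.asarray(values, dtype=float)
    grid = np.arange(start_doy, start_doy + values.size)
    return DailyCurve(station, year, grid, values)


def triangular_curve(baseline=0.2, peak=1.0, t1=140, t2=150, t3=160,
                     pad_before=0, pad_after=0) -> DailyCurve:
    """Piecewise-linear single pulse with optional flat padding."""
    up = np.linspace(baseline, peak, t2 - t1 + 1)
    down = np.linspace(peak, baseline, t3 - t2 + 1)[1:]
    vals = np.concatenate([np.full(pad_before, baseline), up, down,
                           np.full(pad_after, baseline)])
    return make_curve(vals, start_doy=t1 - pad_before)


@pytest.fixture
def simple_chl_series():
    doys = np.arange(100, 230, 10)
    return ChlSeries("ST1", 2015, doys, np.full(doys.size, 0.3))


def ice_series_from(concs, year=2015, station="ST1") -> IceSeries:
    conc = np.full(366 if year % 4 == 0 else 365, np.nan)
    conc[:len(concs)] = concs
    return IceSeries(station, year, conc)


def constant_ice(value, year=2015, station="ST1") -> IceSeries:
    n = 366 if year % 4 == 0 else 365
    return IceSeries(station, year, np.full(n, float(value)))


def profile(props_by_depth, station="ST1", year=2015, total=4.0, doy=196):
    """Pigment profile with prescribed proportion at each depth."""
    return [
        PigmentSample(station, year, doy, depth, chl=total * (1 - p), pheo=total * p)
        for depth, p in props_by_depth
    ]
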