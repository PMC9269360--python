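"""Phenology chain: ice masking, QC, smoothing, bloom detection, staging."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloomstage import phenology as ph
from bloomstage.config import RunConfig
from bloomstage.types import BloomCycle, ChlSeries, Stage

from conftest import constant_ice, ice_series_from, make_curve, triangular_curve


class TestIceMasking:
    def test_observation_above_threshold_removed(self):
        s = ChlSeries("ST1", 2015, [90, 100, 110], [0.5, 0.6, 0.7])
        concs = np.zeros(365)
        concs[99] = 40.0
        masked = ph.mask_ice_days(s, ice_series_from(concs), 15.0)
        assert list(masked.doys) == [90, 110]
        assert masked.masked_doys == {100}

    def test_exactly_at_threshold_retained(self):
        s = ChlSeries("ST1", 2015, [100], [0.5])
        concs = np.zeros(365)
        concs[99] = 15.0
        masked = ph.mask_ice_days(s, ice_series_from(concs), 15.0)
        assert list(masked.doys) == [100]

    def test_zero_ice_changes_nothing(self):
        s = ChlSeries("ST1", 2015, [90, 100], [0.5, 0.6])
        masked = ph.mask_ice_days(s, constant_ice(0))
        assert list(masked.doys) == [90, 100]

    def test_missing_ice_days_retained(self):
        s = ChlSeries("ST1", 2015, [90, 100], [0.5, 0.6])
        concs = np.full(365, np.nan)
        masked = ph.mask_ice_days(s, ice_series_from(concs))
        assert masked.n_obs == 2

    def test_mismatched_station_year_is_a_pairing_error(self):
        s = ChlSeries("ST1", 2015, [90], [0.5])
        with pytest.raises(ph.PairingError):
            ph.mask_ice_days(s, constant_ice(0, year=2016))


class TestQC:
    def test_too_few_observations(self):
        s = ChlSeries("ST1", 2015, [100, 120, 140, 180, 200], np.ones(5))
        res = ph.qc_series(s)
        assert not res.passed and res.failing_rule == "min_observations"

    def test_long_gap_fails_even_with_many_observations(self):
        doys = np.concatenate([np.arange(100, 170, 5), np.arange(200, 280, 5)])
        s = ChlSeries("ST1", 2015, doys, np.ones(doys.size))
        res = ph.qc_series(s)
        assert not res.passed and res.failing_rule == "max_gap"

    def test_window_coverage_rule(self):
        doys = np.arange(100, 300, 20)  # only 174-219 hits: 180, 200 -> 2 obs
        s = ChlSeries("ST1", 2015, doys, np.ones(doys.size))
        res = ph.qc_series(s)
        assert not res.passed and res.failing_rule == "window_coverage"

    def test_evenly_spaced_series_passes(self):
        doys = np.arange(100, 300, 10)  # 20 obs, 10-day gaps, 5 in window
        s = ChlSeries("ST1", 2015, doys, np.ones(doys.size))
        assert ph.qc_series(s).passed

    def test_empty_series_fails_min_observations(self):
        s = ChlSeries("ST1", 2015, [], [])
        assert ph.qc_series(s).failing_rule == "min_observations"

    def test_seasonal_bound_gap_checked_when_configured(self):
        doys = np.arange(150, 300, 10)
        s = ChlSeries("ST1", 2015, doys, np.ones(doys.size))
        cfg = RunConfig(season_bounds=(100, 300))
        res = ph.qc_series(s, cfg)
        assert not res.passed and res.failing_rule == "max_gap"


class TestSmoothing:
    def test_constant_series_maps_to_constant_curve(self, simple_chl_series):
        curve = ph.fit_phenology_curve(simple_chl_series)
        assert np.allclose(curve.values, 0.3)
        assert curve.doy_grid[0] == 100 and curve.doy_grid[-1] == 220

    def test_linear_series_reproduced_exactly(self):
        doys = np.arange(100, 200, 10)
        chl = 0.1 + 0.01 * (doys - 100)
        curve = ph.fit_phenology_curve(ChlSeries("ST1", 2015, doys, chl))
        expected = 0.1 + 0.01 * (curve.doy_grid - 100)
        assert np.allclose(curve.values, expected, atol=1e-9)

    def test_daily_grid_is_gap_free_and_never_extrapolates(self, simple_chl_series):
        curve = ph.fit_phenology_curve(simple_chl_series)
        assert np.all(np.diff(curve.doy_grid) == 1)

    def test_span_below_three_points_rejected(self):
        s = ChlSeries("ST1", 2015, np.arange(100, 200, 10), np.ones(10))
        with pytest.raises(ValueError, match="3 points"):
            ph.fit_phenology_curve(s, span=0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_curve_stays_within_observed_range(self, seed):
        rng = np.random.default_rng(seed)
        doys = np.sort(rng.choice(np.arange(100, 250), size=30, replace=False))
        chl = 0.5 + 2 * np.exp(-0.5 * ((doys - 170) / 15) ** 2)
        chl = chl * rng.lognormal(0, 0.15, chl.size)
        curve = ph.fit_phenology_curve(ChlSeries("ST1", 2015, doys, chl))
        assert curve.values.min() >= chl.min() - 1e-9
        assert curve.values.max() <= chl.max() + 1e-9


# --- brute-force bloom segmentation oracle ---------------------------------

def oracle_cycles(values, rise_min=0.5):
    """Naive day-by-day re-derivation of the segmentation rules: collapse
    plateaus, find strict interior minima, place the final boundary (a
    descending terminal run counts as a minimum at its first day, confirmed
    only when it lasts at least two days), then apply the qualification and
    continuation-merge rules segment by segment."""
    n = len(values)
    if n == 0:
        return []
    # plateau runs as (first_index, value), scanned day by day
    runs = []
    for i in range(n):
        if i == 0 or values[i] != values[i - 1]:
            runs.append([i, values[i]])
    # interior strict local minima
    bounds = {0}
    for k in range(1, len(runs) - 1):
        if runs[k - 1][1] > runs[k][1] < runs[k + 1][1]:
            bounds.add(runs[k][0])
    if len(runs) >= 2 and runs[-1][1] < runs[-2][1]:
        final = runs[-1][0]
        confirmed = final < n - 1
    else:
        final = n - 1
        confirmed = False
    bounds.add(final)
    bounds = sorted(b for b in bounds if b <= final)
    cycles = []
    current = None
    for a, b in zip(bounds[:-1], bounds[1:]):
        rise = max(values[a:b + 1]) - values[a]
        if rise >= rise_min:
            if current:
                cycles.append(current)
            current = [a, b]
        elif current and values[a] > values[current[0]]:
            current[1] = b
        else:
            if current:
                cycles.append(current)
            current = None
    if current:
        cycles.append(current)
    out = []
    for a, b in cycles:
        seg = values[a:b + 1]
        t2 = a + int(np.argmax(seg))
        out.append((a, t2, b, b == n - 1 and not confirmed))
    return out


class TestBloomDetection:
    def test_flat_curve_has_no_cycles(self):
        assert ph.detect_bloom_cycles(make_curve(np.full(60, 0.3))) == []

    def test_triangular_pulse_yields_one_cycle(self):
        curve = triangular_curve(0.2, 1.0, 140, 150, 160)
        (c,) = ph.detect_bloom_cycles(curve)
        assert (c.t1, c.t2, c.t3) == (140, 150, 160)
        assert c.amplitude == pytest.approx(0.8)
        assert c.chl_t2 == pytest.approx(1.0)

    def test_sub_threshold_rise_ignored(self):
        curve = triangular_curve(0.2, 0.6, 140, 150, 160)
        assert ph.detect_bloom_cycles(curve) == []

    def test_two_separated_pulses_yield_two_cycles(self):
        up1 = np.linspace(0.2, 1.0, 11)
        down1 = np.linspace(1.0, 0.2, 11)[1:]
        up2 = np.linspace(0.2, 0.9, 11)[1:]
        down2 = np.linspace(0.9, 0.2, 11)[1:]
        curve = make_curve(np.concatenate([up1, down1, up2, down2]), start_doy=140)
        c1, c2 = ph.detect_bloom_cycles(curve)
        assert c1.t3 == c2.t1  # shared boundary day
        assert c1.t1 < c1.t2 <= c1.t3 < c2.t2 <= c2.t3

    def test_sub_threshold_shoulder_merges_into_preceding_bloom(self):
        # big bloom, dip that stays above its start, small shoulder
        vals = np.concatenate([
            np.linspace(0.2, 1.2, 11),       # rise 1.0
            np.linspace(1.2, 0.6, 7)[1:],    # dip to 0.6 > 0.2
            np.linspace(0.6, 0.9, 4)[1:],    # shoulder rise 0.3 < 0.5
            np.linspace(0.9, 0.1, 9)[1:],    # final decline
        ])
        curve = make_curve(vals, start_doy=140)
        cycles = ph.detect_bloom_cycles(curve)
        assert len(cycles) == 1
        assert cycles[0].t3 == int(curve.doy_grid[-1])

    def test_sub_threshold_bump_after_return_to_baseline_is_no_bloom(self):
        vals = np.concatenate([
            np.linspace(0.2, 1.2, 11),
            np.linspace(1.2, 0.15, 11)[1:],  # back below start
            np.linspace(0.15, 0.45, 4)[1:],  # bump rise 0.3
            np.linspace(0.45, 0.15, 4)[1:],
        ])
        cycles = ph.detect_bloom_cycles(make_curve(vals, start_doy=140))
        assert len(cycles) == 1
        assert cycles[0].t2 == 150

    def test_peak_plateau_resolves_to_earliest_day(self):
        vals = np.concatenate([np.linspace(0.2, 1.0, 6),
                               np.full(3, 1.0), np.linspace(1.0, 0.2, 6)[1:]])
        (c,) = ph.detect_bloom_cycles(make_curve(vals, start_doy=100))
        assert c.t2 == 105

    def test_truncated_series_flagged(self):
        vals = np.linspace(0.2, 1.2, 21)  # still rising at the end
        (c,) = ph.detect_bloom_cycles(make_curve(vals, start_doy=100))
        assert c.truncated_end and c.t2 == c.t3 == 120

    def test_cycle_ordering_and_amplitude_invariants(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            vals = np.abs(rng.normal(0.5, 0.5, 80)).round(1)
            cycles = ph.detect_bloom_cycles(make_curve(vals))
            t1s = [c.t1 for c in cycles]
            assert t1s == sorted(t1s)
            assert all(c.amplitude >= 0.5 for c in cycles)
            assert all(c.t1 < c.t2 <= c.t3 for c in cycles)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 4), min_size=2, max_size=60))
    def test_matches_brute_force_oracle_on_small_curves(self, tenths):
        vals = np.asarray(tenths, dtype=float) / 2.0  # step 0.5 in units of rise
        curve = make_curve(vals, start_doy=1)
        got = [(c.t1 - 1, c.t2 - 1, c.t3 - 1, c.truncated_end)
               for c in ph.detect_bloom_cycles(curve, 1.0)]
        assert got == oracle_cycles(list(vals), 1.0)


class TestStageClassification:
    CYCLE = BloomCycle(140, 150, 160, 0.2, 1.0, 0.2)

    @pytest.mark.parametrize("doy,expected", [
        (135, Stage.NB),   # before t1
        (140, Stage.EB),   # start day
        (150, Stage.EB),   # peak day counts as Early
        (151, Stage.PB),
        (160, Stage.PB),   # end day
        (161, Stage.NB),
    ])
    def test_equation_boundaries(self, doy, expected):
        assert ph.classify_stage([self.CYCLE], doy) is expected

    def test_no_cycles_means_no_bloom(self):
        assert ph.classify_stage([], 150) is Stage.NB

    def test_out_of_coverage_is_an_error_not_nb(self):
        curve = triangular_curve()
        with pytest.raises(ph.OutOfCoverageError):
            ph.classify_stage([self.CYCLE], 300, curve)

    def test_every_grid_day_gets_exactly_one_stage(self):
        rng = np.random.default_rng(3)
        vals = np.abs(rng.normal(0.5, 0.5, 120)).round(1)
        curve = make_curve(vals)
        cycles = ph.detect_bloom_cycles(curve)
        for doy in curve.doy_grid:
            stage = ph.classify_stage(cycles, int(doy), curve)
            assert stage in (Stage.NB, Stage.EB, Stage.PB)
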