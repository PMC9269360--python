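"""Breakup detection, spring open-water classification, AMOC changepoint."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloomstage import seaice
from bloomstage.types import BreakupResult, IceClass

from conftest import constant_ice, ice_series_from


def winter_series(breakup_start, run_len=300, level=90.0, low=10.0):
    concs = np.full(365, low)
    concs[:breakup_start - 1] = level
    return ice_series_from(concs)


class TestBreakup:
    def test_first_two_day_run_below_threshold(self):
        ice = winter_series(100)  # 90% through DOY 99, 10% from DOY 100
        res = seaice.breakup_doy(ice)
        assert res.breakup_doy == 100 and not res.no_ice_flag

    def test_all_open_water_year_has_no_breakup(self):
        res = seaice.breakup_doy(constant_ice(0))
        assert res.no_ice_flag and res.breakup_doy is None

    def test_single_day_dip_does_not_satisfy_the_run(self):
        concs = np.full(365, 90.0)
        concs[89] = 10.0          # one-day dip at DOY 90
        concs[119:] = 5.0         # persistent drop from DOY 120
        res = seaice.breakup_doy(ice_series_from(concs))
        assert res.breakup_doy == 120

    def test_early_winter_open_water_is_not_breakup(self):
        concs = np.full(365, 90.0)
        concs[59:70] = 0.0        # open-water episode DOY 60-70
        concs[139:] = 5.0         # real breakup DOY 140
        res = seaice.breakup_doy(ice_series_from(concs))
        assert res.breakup_doy == 140

    def test_values_after_the_run_are_irrelevant(self):
        a = np.full(365, 90.0); a[99:] = 10.0
        b = a.copy(); b[150:] = 80.0  # ice returns later
        res_a = seaice.breakup_doy(ice_series_from(a))
        res_b = seaice.breakup_doy(ice_series_from(b))
        assert res_a.breakup_doy == res_b.breakup_doy == 100

    def test_no_valid_data_is_an_error(self):
        with pytest.raises(seaice.InsufficientDataError):
            seaice.breakup_doy(ice_series_from(np.full(365, np.nan)))


class TestConcentrationClass:
    def make(self, zero_days):
        concs = np.full(365, 80.0)
        for d in zero_days:
            concs[d - 1] = 0.0
        return ice_series_from(concs)

    def test_eleven_day_zero_run_in_window_is_low(self):
        assert seaice.concentration_ice_class(
            self.make(range(70, 81))) is IceClass.LOW

    def test_exactly_five_day_run_stays_high(self):
        assert seaice.concentration_ice_class(
            self.make(range(70, 75))) is IceClass.HIGH

    def test_six_day_run_is_low(self):
        assert seaice.concentration_ice_class(
            self.make(range(70, 76))) is IceClass.LOW

    def test_full_cover_defaults_high(self):
        assert seaice.concentration_ice_class(constant_ice(100)) is IceClass.HIGH

    def test_zero_run_outside_window_ignored(self):
        assert seaice.concentration_ice_class(
            self.make(range(130, 145))) is IceClass.HIGH

    def test_missing_days_break_runs(self):
        concs = np.full(365, 80.0)
        concs[69:80] = 0.0
        concs[74] = np.nan  # split the run into 5 + 5
        assert seaice.concentration_ice_class(
            ice_series_from(concs)) is IceClass.HIGH

    def test_sub_half_percent_counts_as_zero(self):
        concs = np.full(365, 80.0)
        concs[69:80] = 0.4  # rounds to 0 at integer precision
        assert seaice.concentration_ice_class(
            ice_series_from(concs)) is IceClass.LOW


def oracle_best_split(x, min_seg=2):
    """Enumerate every split; return the SSE-minimizing first-segment length."""
    best, best_sse = None, float("inf")
    for k in range(min_seg, len(x) - min_seg + 1):
        sse = 0.0
        for seg in (x[:k], x[k:]):
            m = sum(seg) / len(seg)
            sse += sum((v - m) ** 2 for v in seg)
        if sse < best_sse:
            best, best_sse = k, sse
    return best, best_sse


class TestChangepoint:
    def test_hand_worked_example(self):
        res = seaice.amoc_changepoint([150, 148, 152, 110, 112, 108])
        assert res.split_index == 3
        assert res.pre_mean == pytest.approx(150.0)
        assert res.post_mean == pytest.approx(110.0)
        assert res.doy_threshold == pytest.approx(130.0)

    def test_constant_sequence_has_no_split(self):
        res = seaice.amoc_changepoint([140] * 6)
        assert res.split_index is None
        assert res.doy_threshold == pytest.approx(140.0)

    def test_too_short_sequence_is_an_error(self):
        with pytest.raises(seaice.InsufficientDataError):
            seaice.amoc_changepoint([120, 130, 140])

    def test_none_entries_excluded_before_fit(self):
        res = seaice.amoc_changepoint([150, None, 148, 152, 110, 112, 108])
        assert res.split_index == 3

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(60, 200), min_size=4, max_size=12))
    def test_accepted_split_matches_brute_force_enumeration(self, doys):
        res = seaice.amoc_changepoint(doys)
        k, sse = oracle_best_split([float(d) for d in doys])
        if res.split_index is not None:
            assert res.split_index == k
            # and no alternative split does better
            for alt in range(2, len(doys) - 1):
                a, b = np.array(doys[:alt], float), np.array(doys[alt:], float)
                alt_sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
                assert sse <= alt_sse + 1e-9

    def test_shifting_all_dates_shifts_threshold_exactly(self):
        base = [150.0, 148.0, 152.0, 110.0, 112.0, 108.0]
        r0 = seaice.amoc_changepoint(base)
        r7 = seaice.amoc_changepoint([d + 7 for d in base])
        assert r7.doy_threshold == pytest.approx(r0.doy_threshold + 7)

    def test_step_recovery_under_noise(self):
        """40-day step with SD-5 noise over 7 years: the split year is found
        in at least 90% of 500 replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(500):
            x = np.concatenate([rng.normal(150, 5, 4), rng.normal(110, 5, 3)])
            hits += seaice.amoc_changepoint(x).split_index == 4
        assert hits / 500 >= 0.90


class TestBreakupClass:
    @pytest.mark.parametrize("doy,thr,expected", [
        (110, 130.0, IceClass.LOW),
        (150, 130.0, IceClass.HIGH),
        (130, 130.0, IceClass.HIGH),  # at the threshold -> not before it
    ])
    def test_before_threshold_is_low(self, doy, thr, expected):
        res = BreakupResult("ST1", 2015, doy)
        assert seaice.breakup_ice_class(res, thr) is expected

    def test_no_ice_year_is_the_low_extreme(self):
        res = BreakupResult("ST1", 2018, None, no_ice_flag=True)
        assert seaice.breakup_ice_class(res, 130.0) is IceClass.LOW
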