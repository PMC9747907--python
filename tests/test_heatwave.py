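"""Heatwave detection against brute-force oracles, plus window exposure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatburden.heatwave import (
    HeatwaveDetector,
    compute_threshold,
    detect_heatwaves,
    exposure_window,
    heatwave_days_by_year,
)


def oracle_heatwave_days(exceed, min_duration):
    """Independent run scan: a day is a heatwave day iff it lies inside a
    maximal run of >= min_duration consecutive exceedance days."""
    n = len(exceed)
    out = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if exceed[i]:
            j = i
            while j < n and exceed[j]:
                j += 1
            if j - i >= min_duration:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def oracle_exposure(hw_days, window):
    n = len(hw_days)
    return np.array([any(hw_days[max(0, d - window + 1) : d + 1]) for d in range(n)])


class TestThreshold:
    def test_constant_series(self, grid_factory):
        g = grid_factory(np.full((1, 400), 30.0))
        assert compute_threshold(g).iloc[0] == 30.0

    def test_linear_interpolation_convention(self, grid_factory):
        # 100 warm-season days valued 1..100: the 0.9 quantile interpolates
        # between the 90th and 91st order statistics -> 90.1
        g = grid_factory(np.arange(1, 101)[None, :], start="2015-05-01")
        thr = compute_threshold(g, percentile=0.90)
        assert thr.iloc[0] == pytest.approx(90.1, abs=1e-9)

    def test_pools_warm_season_only(self, grid_factory):
        vals = np.full((1, 730), 10.0)
        g = grid_factory(vals, start="2015-01-01")
        warm = np.isin(g.month_of_day(), [5, 6, 7, 8, 9, 10])
        vals[0, warm] = 25.0
        g = grid_factory(vals, start="2015-01-01")
        assert compute_threshold(g).iloc[0] == 25.0

    def test_errors(self, grid_factory):
        g = grid_factory(np.zeros((1, 30)))
        with pytest.raises(ValueError):
            compute_threshold(g, warm_months=())
        with pytest.raises(ValueError):
            compute_threshold(g, percentile=1.5)
        with pytest.raises(ValueError):
            # January-only series has no warm-season days
            compute_threshold(g, warm_months=(7,))


class TestDetection:
    def test_isolated_exceedances_are_not_heatwaves(self, grid_factory):
        g = grid_factory([[35, 30, 36, 30]])
        mask = detect_heatwaves(g, pd.Series([34.0], index=[0]))
        assert not mask.mask.values.any()
        assert len(mask.events) == 0

    def test_two_events_with_durations(self, grid_factory):
        g = grid_factory([[35, 36, 30, 35, 36, 37]])
        mask = detect_heatwaves(g, pd.Series([34.0], index=[0]))
        assert list(np.flatnonzero(mask.mask.values[0])) == [0, 1, 3, 4, 5]
        assert sorted(mask.events["duration"]) == [2, 3]

    def test_threshold_above_maximum(self, grid_factory):
        g = grid_factory([[35, 36, 37, 38]])
        mask = detect_heatwaves(g, pd.Series([50.0], index=[0]))
        assert not mask.mask.values.any()

    def test_exceedance_is_strict(self, grid_factory):
        g = grid_factory([[34, 34, 34]])
        mask = detect_heatwaves(g, pd.Series([34.0], index=[0]))
        assert not mask.mask.values.any()

    def test_missing_threshold_errors(self, grid_factory):
        g = grid_factory(np.zeros((2, 10)))
        with pytest.raises(ValueError):
            detect_heatwaves(g, pd.Series([30.0], index=[0]))

    @pytest.mark.parametrize("min_duration", [1, 2, 3])
    def test_matches_bruteforce_on_random_series(self, grid_factory, min_duration):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(5, 400)
            vals = rng.normal(30, 5, size=(1, n))
            g = grid_factory(vals)
            thr = pd.Series([np.quantile(vals, 0.9)], index=[0])
            mask = detect_heatwaves(g, thr, min_duration)
            expected = oracle_heatwave_days(vals[0] > thr.iloc[0], min_duration)
            assert np.array_equal(mask.mask.values[0], expected)
            # every flagged day belongs to a run of >= min_duration
            for _, ev in mask.events.iterrows():
                assert ev["duration"] >= min_duration

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_lowering_threshold_never_reduces_heatwave_days(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(30, 5, size=(1, 120))
        from tests.conftest import make_grid

        g = make_grid(vals)
        hi = detect_heatwaves(g, pd.Series([32.0], index=[0])).mask.values.sum()
        lo = detect_heatwaves(g, pd.Series([28.0], index=[0])).mask.values.sum()
        assert lo >= hi


class TestExposure:
    def test_window_arithmetic(self, grid_factory):
        vals = np.full((1, 30), 20.0)
        vals[0, 10:12] = 40.0
        g = grid_factory(vals)
        mask = detect_heatwaves(g, pd.Series([35.0], index=[0]))
        exposed = exposure_window(mask, 7).values[0]
        assert set(np.flatnonzero(exposed)) == set(range(10, 18))

    def test_empty_mask_all_false(self, grid_factory):
        g = grid_factory(np.zeros((2, 50)))
        mask = detect_heatwaves(g, pd.Series([10.0, 10.0], index=[0, 1]))
        assert not exposure_window(mask, 7).values.any()

    def test_window_one_is_identity(self, grid_factory):
        rng = np.random.default_rng(0)
        g = grid_factory(rng.normal(30, 5, size=(1, 200)))
        mask = detect_heatwaves(g, pd.Series([32.0], index=[0]))
        assert np.array_equal(exposure_window(mask, 1).values, mask.mask.values)

    def test_matches_bruteforce_window(self, grid_factory):
        rng = np.random.default_rng(7)
        for window in (3, 7, 10):
            vals = rng.normal(30, 5, size=(1, 300))
            g = grid_factory(vals)
            mask = detect_heatwaves(g, pd.Series([33.0], index=[0]))
            got = exposure_window(mask, window).values[0]
            assert np.array_equal(got, oracle_exposure(mask.mask.values[0], window))

    def test_adding_heatwave_day_is_monotone(self, grid_factory):
        rng = np.random.default_rng(3)
        vals = rng.normal(30, 5, size=(1, 120))
        g = grid_factory(vals)
        mask = detect_heatwaves(g, pd.Series([33.0], index=[0]))
        before = exposure_window(mask, 7).values.copy()
        aug = mask.mask.copy()
        free = np.flatnonzero(~aug.values[0])
        aug.values[0, free[len(free) // 2]] = True
        mask.mask = aug
        after = exposure_window(mask, 7).values
        assert (after | before).sum() == after.sum()  # before subset of after


class TestYearlyCounts:
    def test_single_event_count(self, grid_factory):
        vals = np.full((1, 365), 20.0)
        vals[0, 200:203] = 40.0
        g = grid_factory(vals, start="2015-01-01")
        mask = detect_heatwaves(g, pd.Series([35.0], index=[0]))
        counts = mask.days_by_cell_year()
        assert counts.loc[0, 2015] == 3

    def test_national_mean_conserves_total(self, grid_factory):
        rng = np.random.default_rng(5)
        vals = rng.normal(30, 5, size=(4, 730))
        g = grid_factory(vals, start="2015-01-01")
        det = HeatwaveDetector().fit(g)
        mask = det.transform(g)
        table = heatwave_days_by_year(mask)
        cells = table.drop(index="national")
        for y in cells.columns:
            assert table.loc["national", y] * len(cells) == pytest.approx(cells[y].sum())

    def test_population_weighted_option(self, grid_factory):
        vals = np.full((2, 400), 20.0)
        vals[0, 100:110] = 40.0  # only cell 0 has heatwaves
        g = grid_factory(vals, start="2015-01-01")
        mask = detect_heatwaves(g, pd.Series([35.0, 35.0], index=[0, 1]))
        years = mask.days_by_cell_year().columns
        pop = pd.DataFrame(
            {y: [9.0, 1.0] for y in years}, index=[0, 1]
        )
        weighted = heatwave_days_by_year(mask, population=pop)
        unweighted = heatwave_days_by_year(mask)
        assert weighted.loc["national", 2015] > unweighted.loc["national", 2015]
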