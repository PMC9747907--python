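"""Heatwave detection and last-gestational-week exposure.

A heatwave is defined as two or more consecutive days with daily maximum
temperature strictly exceeding the cell's 90th percentile of warm-season
(May-October) temperatures pooled over the study period.  Exposure on
delivery day *d* means at least one heatwave day in the trailing window
[d-6, d].  Thresholds are computed from warm-season days only, but runs are
detected on the full daily series; flagged days outside the warm season are
kept (they accrue no burden because baselines exist only for warm-season
months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from heatburden.config import DEFAULT_WARM_MONTHS
from heatburden.containers import TemperatureGrid

#: quantile convention used throughout (recorded in output metadata)
QUANTILE_METHOD = "linear"


def compute_threshold(
    grid: TemperatureGrid,
    warm_months: tuple[int, ...] = DEFAULT_WARM_MONTHS,
    percentile: float = 0.90,
) -> pd.Series:
    """Per-cell temperature threshold: the given percentile of warm-season tmax.

    Warm-season daily values are pooled over all study years per cell;
    quantiles use linear interpolation between order statistics.
    """
    if not warm_months:
        raise ValueError("warm_months must be non-empty")
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must be in (0, 1)")
    in_season = np.isin(grid.month_of_day(), list(warm_months))
    if not in_season.any():
        raise ValueError("no warm-season days in the series")
    warm = grid.values[:, in_season]
    thr = np.quantile(warm, percentile, axis=1, method=QUANTILE_METHOD)
    s = pd.Series(thr, index=grid.cells, name="threshold")
    s.attrs["quantile_method"] = QUANTILE_METHOD
    return s


def _runs_bool(exceed: np.ndarray, min_duration: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Mask of days in exceedance runs >= min_duration, plus (start, stop) pairs."""
    padded = np.concatenate(([False], exceed, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)  # exclusive
    mask = np.zeros(exceed.shape, dtype=bool)
    events = []
    for a, b in zip(starts, stops):
        if b - a >= min_duration:
            mask[a:b] = True
            events.append((a, b))
    return mask, events


@dataclass
class HeatwaveMask:
    """Per cell-day heatwave indicator with the derived event list.

    ``mask`` is a boolean DataArray (cell, time); ``events`` lists each
    maximal run as (cell, start, end, duration); every flagged day belongs to
    a run of at least ``min_duration`` consecutive flagged days.
    """

    mask: xr.DataArray
    events: pd.DataFrame
    min_duration: int = 2
    thresholds: pd.Series | None = field(default=None, repr=False)

    @property
    def time_index(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.mask["time"].values)

    def days_by_cell_year(self) -> pd.DataFrame:
        """Integer heatwave-day counts, index=cell, columns=year."""
        years = self.time_index.year
        df = pd.DataFrame(
            self.mask.values.astype(int).T, index=years, columns=self.mask["cell"].values
        )
        return df.groupby(level=0).sum().T.rename_axis(index="cell", columns="year")

    def to_netcdf(self, path: str | Path) -> None:
        ds = self.mask.astype("uint8").to_dataset(name="heatwave_day")
        ds.attrs.update(min_duration=self.min_duration)
        ds.to_netcdf(path, engine="scipy")


def detect_heatwaves(
    grid: TemperatureGrid, thresholds: pd.Series, min_duration: int = 2
) -> HeatwaveMask:
    """Flag heatwave days: maximal runs of >= min_duration consecutive days
    with tmax strictly above the cell threshold.

    Runs are evaluated on the full daily series and may cross month and year
    boundaries.  Exceedance is strict; a day exactly at the threshold is not
    an event.
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    missing = [c for c in grid.cells if c not in thresholds.index]
    if missing:
        raise ValueError(f"threshold missing for cells: {missing[:5]}")

    thr = thresholds.loc[grid.cells].values[:, None]
    exceed = grid.values > thr
    mask = np.zeros_like(exceed)
    rows = []
    times = grid.time_index
    for i, cell in enumerate(grid.cells):
        m, events = _runs_bool(exceed[i], min_duration)
        mask[i] = m
        for a, b in events:
            rows.append((cell, times[a], times[b - 1], b - a))
    events_df = pd.DataFrame(rows, columns=["cell", "start", "end", "duration"])
    da = xr.DataArray(mask, coords=grid.data.coords, dims=("cell", "time"), name="heatwave_day")
    return HeatwaveMask(mask=da, events=events_df, min_duration=min_duration, thresholds=thresholds)


def exposure_window(mask: HeatwaveMask, window_days: int = 7) -> xr.DataArray:
    """Exposure indicator: any heatwave day within the trailing window.

    ``exposed[c, d]`` is true iff at least one heatwave day falls in
    ``[d - window_days + 1, d]``; at the series start the window truncates to
    the available days.  The default 7-day window is the final gestational
    week, days (d-6)..d.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    vals = mask.mask.values.astype(np.int64)
    cs = np.cumsum(vals, axis=1)
    shifted = np.zeros_like(cs)
    if vals.shape[1] > window_days:
        shifted[:, window_days:] = cs[:, :-window_days]
    exposed = (cs - shifted) > 0
    return xr.DataArray(
        exposed, coords=mask.mask.coords, dims=("cell", "time"), name="exposed"
    ).assign_attrs(window_days=window_days)


def heatwave_days_by_year(
    mask: HeatwaveMask, population: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Annual heatwave-day counts per cell plus a national summary row.

    The national value is the unweighted mean over cells; if ``population``
    (cell x year) is given, a population-weighted mean using each year's
    weights is reported instead.
    """
    counts = mask.days_by_cell_year()
    if population is None:
        national = counts.mean(axis=0)
    else:
        pop = population.reindex(index=counts.index, columns=counts.columns)
        national = (counts * pop).sum(axis=0) / pop.sum(axis=0)
    out = counts.copy()
    out.loc["national"] = national
    return out


class HeatwaveDetector:
    """Threshold-fitting + detection convenience with a fit/transform API.

    ``fit`` learns per-cell percentile thresholds from a (reference) grid;
    ``transform`` detects heatwaves on any grid with the same cells using
    those thresholds — the pattern used for scenario runs, where thresholds
    fitted on the bias-corrected factual series are applied unchanged to the
    counterfactual.
    """

    def __init__(
        self,
        percentile: float = 0.90,
        warm_months: tuple[int, ...] = DEFAULT_WARM_MONTHS,
        min_duration: int = 2,
        window_days: int = 7,
    ) -> None:
        self.percentile = percentile
        self.warm_months = tuple(warm_months)
        self.min_duration = min_duration
        self.window_days = window_days

    def fit(self, grid: TemperatureGrid) -> "HeatwaveDetector":
        self.thresholds_ = compute_threshold(grid, self.warm_months, self.percentile)
        return self

    def transform(self, grid: TemperatureGrid) -> HeatwaveMask:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("HeatwaveDetector is not fitted")
        return detect_heatwaves(grid, self.thresholds_, self.min_duration)

    def fit_transform(self, grid: TemperatureGrid) -> HeatwaveMask:
        return self.fit(grid).transform(grid)
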