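"""Empirical quantile-mapping bias correction.

Simulated daily-tmax series are calibrated against an observed series per
cell and calendar month: paired empirical quantiles over a common
calibration period define a monotone mapping (linear interpolation between
anchors, linear extrapolation beyond the outermost anchors so the upper
tail — where heatwaves live — is not clamped).  The map is fitted on the
factual run of each climate model and applied unchanged to that model's
counterfactual run; the counterfactual is never fitted against observations
directly, which would erase the attribution signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from heatburden.containers import TemperatureGrid
from heatburden.heatwave import QUANTILE_METHOD


def _interp_with_tails(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp plus linear extrapolation from the two outermost anchors."""
    if xp[-1] == xp[0]:  # degenerate source distribution: additive shift
        return x + (fp[len(fp) // 2] - xp[0])
    y = np.interp(x, xp, fp)
    lo, hi = x < xp[0], x > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0]) if xp[1] > xp[0] else 1.0
        y[lo] = fp[0] + slope * (x[lo] - xp[0])
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2]) if xp[-1] > xp[-2] else 1.0
        y[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return y


@dataclass
class QuantileMapper:
    """Per cell x calendar month monotone quantile mapping.

    ``source_q`` and ``target_q`` hold paired empirical quantiles with shape
    (n_cells, 12, n_quantiles) at common anchor levels ``levels``.
    """

    cells: np.ndarray
    levels: np.ndarray
    source_q: np.ndarray
    target_q: np.ndarray

    def __post_init__(self) -> None:
        if self.source_q.shape != self.target_q.shape:
            raise ValueError("source and target quantile tables must have equal shape")

    @classmethod
    def from_grids(
        cls,
        simulated: TemperatureGrid,
        observed: TemperatureGrid,
        n_quantiles: int = 99,
    ) -> "QuantileMapper":
        if n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")
        if not np.array_equal(simulated.cells, observed.cells):
            raise ValueError("simulated and observed grids have different cells")
        common = simulated.time_index.intersection(observed.time_index)
        if len(common) == 0:
            raise ValueError("no common calibration period between series")

        levels = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
        sim = simulated.data.sel(time=common).values
        obs = observed.data.sel(time=common).values
        months = common.month.values
        n_cells = sim.shape[0]
        src = np.empty((n_cells, 12, n_quantiles))
        tgt = np.empty((n_cells, 12, n_quantiles))
        for m in range(1, 13):
            sel = months == m
            if not sel.any():
                src[:, m - 1, :] = np.nan
                tgt[:, m - 1, :] = np.nan
                continue
            src[:, m - 1, :] = np.quantile(sim[:, sel], levels, axis=1, method=QUANTILE_METHOD).T
            tgt[:, m - 1, :] = np.quantile(obs[:, sel], levels, axis=1, method=QUANTILE_METHOD).T
        return cls(cells=simulated.cells.copy(), levels=levels, source_q=src, target_q=tgt)

    def transform(self, series: TemperatureGrid) -> TemperatureGrid:
        missing = set(series.cells) - set(self.cells)
        if missing:
            raise ValueError(f"cells absent from bias-correction map: {sorted(missing)[:5]}")
        cell_pos = {c: i for i, c in enumerate(self.cells)}
        months = series.month_of_day()
        vals = series.values.copy()
        for i, cell in enumerate(series.cells):
            k = cell_pos[cell]
            for m in range(1, 13):
                sel = months == m
                if not sel.any():
                    continue
                xp = self.source_q[k, m - 1]
                fp = self.target_q[k, m - 1]
                if np.isnan(xp).any():
                    raise ValueError(f"map has no anchors for calendar month {m}")
                vals[i, sel] = _interp_with_tails(vals[i, sel], xp, fp)
        da = xr.DataArray(
            vals, coords=series.data.coords, dims=("cell", "time"), name="tmax"
        ).assign_attrs(bias_correction="empirical quantile mapping per cell-month")
        return TemperatureGrid(data=da, scenario=series.scenario, member=series.member)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: cell, month, level, source_value, target_value."""
        n_cells, _, n_q = self.source_q.shape
        cells = np.repeat(self.cells, 12 * n_q)
        months = np.tile(np.repeat(np.arange(1, 13), n_q), n_cells)
        levels = np.tile(self.levels, 12 * n_cells)
        return pd.DataFrame(
            {
                "cell": cells,
                "month": months,
                "level": levels,
                "source_value": self.source_q.ravel(),
                "target_value": self.target_q.ravel(),
            }
        )


def fit_bias_correction(
    simulated_factual: TemperatureGrid,
    observed: TemperatureGrid,
    n_quantiles: int = 99,
) -> QuantileMapper:
    """Fit the quantile map from a factual run against observations."""
    return QuantileMapper.from_grids(simulated_factual, observed, n_quantiles)


def apply_bias_correction(series: TemperatureGrid, mapper: QuantileMapper) -> TemperatureGrid:
    """Apply a fitted map; the transform is monotone per cell-month, so value
    order within a cell-month is preserved."""
    return mapper.transform(series)
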