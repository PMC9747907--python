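"""Core data containers: gridded temperature series and demographic tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr


@dataclass
class TemperatureGrid:
    """Per-cell daily maximum temperature series with calendar metadata.

    ``data`` is an xarray DataArray with dims ``(cell, time)``; ``time`` is a
    contiguous daily DatetimeIndex with no gaps, values in degC.  ``scenario``
    is one of observed/factual/counterfactual and ``member`` the ensemble
    member index (0 for observed).
    """

    data: xr.DataArray
    scenario: str = "observed"
    member: int = 0

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != ("cell", "time"):
            raise ValueError("data must have dims (cell, time)")
        times = self.time_index
        if len(times) > 1:
            deltas = np.unique(np.diff(times.values).astype("timedelta64[D]"))
            if deltas.size != 1 or deltas[0] != np.timedelta64(1, "D"):
                raise ValueError("time index must be contiguous daily")
        if not np.isfinite(self.data.values).all():
            raise ValueError("temperatures must be finite")

    @property
    def cells(self) -> np.ndarray:
        return self.data["cell"].values

    @property
    def n_cells(self) -> int:
        return self.data.sizes["cell"]

    @property
    def time_index(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].values)

    @property
    def values(self) -> np.ndarray:
        """(n_cells, n_days) float array of daily tmax."""
        return self.data.values

    def month_of_day(self) -> np.ndarray:
        return self.time_index.month.values

    def year_of_day(self) -> np.ndarray:
        return self.time_index.year.values

    def to_netcdf(self, path: str | Path) -> None:
        ds = self.data.to_dataset(name="tmax")
        ds["tmax"].attrs.update(units="degC", long_name="daily maximum temperature")
        ds.attrs.update(scenario=self.scenario, member=int(self.member))
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "TemperatureGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            da = ds["tmax"].load()
            scenario = ds.attrs.get("scenario", "observed")
            member = int(ds.attrs.get("member", 0))
        return cls(data=da, scenario=scenario, member=member)


@dataclass
class DemographicTables:
    """Province-level rate tables plus gridded population.

    population
        DataFrame, index=cell, columns=year: persons.
    birth_rate
        DataFrame, index=province, columns=year: live births per person-year.
    ptb_rate
        DataFrame, index=province, columns=year: preterm fraction of live
        births, in (0, 1).
    birth_month_prop
        DataFrame, index=province, columns=1..12: fraction of the year's live
        births delivered in each calendar month; rows sum to 1.
    province_of_cell
        Series mapping cell id -> province id.
    """

    population: pd.DataFrame
    birth_rate: pd.DataFrame
    ptb_rate: pd.DataFrame
    birth_month_prop: pd.DataFrame
    province_of_cell: pd.Series

    def __post_init__(self) -> None:
        sums = self.birth_month_prop.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("monthly birth proportions must sum to 1 per province")
        for name, tab in (("birth_rate", self.birth_rate), ("ptb_rate", self.ptb_rate)):
            v = tab.values
            if (v < 0).any() or (v > 1).any():
                raise ValueError(f"{name} values must lie in [0, 1]")
        if (self.population.values < 0).any():
            raise ValueError("population must be non-negative")
        missing = set(self.population.index) - set(self.province_of_cell.index)
        if missing:
            raise ValueError(f"cells without a province mapping: {sorted(missing)[:5]}")

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.population.columns]

    @property
    def provinces(self) -> list:
        return list(self.birth_rate.index)

    def live_births(self, year: int) -> pd.Series:
        """Expected live births per cell in ``year`` (Pop x BirthRate)."""
        prov = self.province_of_cell.loc[self.population.index]
        rate = self.birth_rate[year].loc[prov].values
        return self.population[year] * rate

    _TABLES = ("population", "birth_rate", "ptb_rate", "birth_month_prop", "province_of_cell")

    def to_csv(self, directory: str | Path) -> None:
        """Write one CSV per table into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            obj = getattr(self, name)
            obj.to_csv(directory / f"{name}.csv")

    @classmethod
    def from_csv(cls, directory: str | Path) -> "DemographicTables":
        directory = Path(directory)
        kw = {}
        for name in cls._TABLES:
            df = pd.read_csv(directory / f"{name}.csv", index_col=0)
            if name == "province_of_cell":
                kw[name] = df.iloc[:, 0]
            else:
                df.columns = df.columns.astype(int)
                kw[name] = df
        return cls(**kw)
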