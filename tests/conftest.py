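import numpy as np
import pandas as pd
import pytest
import xarray as xr

from heatburden.config import ClimateConfig
from heatburden.containers import DemographicTables, TemperatureGrid


def make_grid(values, start="2015-01-01", scenario="observed", member=0):
    """TemperatureGrid from a raw (n_cells, n_days) array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    times = pd.date_range(start, periods=values.shape[1], freq="D")
    da = xr.DataArray(
        values,
        dims=("cell", "time"),
        coords={"cell": np.arange(values.shape[0]), "time": times},
        name="tmax",
    )
    return TemperatureGrid(data=da, scenario=scenario, member=member)


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture
def small_config():
    return ClimateConfig(
        n_cells=4,
        n_provinces=2,
        year_start=2014,
        year_end=2019,
        noise_sd=3.0,
        noise_autocorr=0.6,
        anthro_trend=0.5,
        n_members=2,
        seed=11,
    )


@pytest.fixture
def tiny_demo_results(tiny_demo):
    """An observed BurdenResult plus a 3-member ensemble on the tiny grid."""
    from heatburden.burden import RiskModel, attributable_ptb, baseline_ptb

    base = baseline_ptb(tiny_demo)
    rng = np.random.default_rng(9)

    def result(member, p):
        exposed = xr.DataArray(
            rng.random(base.daily.shape) < p,
            coords=base.daily.coords,
            dims=("cell", "time"),
        )
        return attributable_ptb(base, exposed, RiskModel(), scenario="factual", member=member)

    return result(0, 0.3), [result(m, 0.2 + 0.1 * m) for m in range(3)]


@pytest.fixture
def tiny_demo():
    """Two cells, one province, two years of hand-set demographic tables."""
    years = [2015, 2016]
    population = pd.DataFrame({2015: [1e6, 5e5], 2016: [1e6, 5e5]}, index=[0, 1])
    birth_rate = pd.DataFrame({2015: [0.01], 2016: [0.01]}, index=[0])
    ptb_rate = pd.DataFrame({2015: [0.07], 2016: [0.07]}, index=[0])
    props = pd.DataFrame([np.full(12, 1 / 12)], index=[0], columns=range(1, 13))
    return DemographicTables(
        population=population,
        birth_rate=birth_rate,
        ptb_rate=ptb_rate,
        birth_month_prop=props,
        province_of_cell=pd.Series([0, 0], index=[0, 1]),
    )
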