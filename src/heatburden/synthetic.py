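"""Synthetic gridded climate and demographic inputs.

The generator emulates only the statistical structure the attribution
analysis depends on: a seasonal daily-tmax cycle with AR(1) weather noise
(enough to produce multi-day exceedance runs, i.e. heatwaves), a factual
ensemble carrying an anthropogenic linear warming trend, a counterfactual
ensemble sharing the identical natural variability but with zero trend, and
internally consistent province-level demographic tables.  Cells are
generated independently; no spatial covariance is imposed because every
downstream computation is cell-wise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from heatburden.config import SCENARIOS, ClimateConfig
from heatburden.containers import DemographicTables, TemperatureGrid

# substream labels: observed noise differs from simulated noise, but factual
# and counterfactual members of the same index share a stream so their
# difference is purely the injected trend.
_STREAM = {"observed": 0, "factual": 1, "counterfactual": 1}
#: mid-July seasonal peak (day-of-year), northern-hemisphere-like
_PEAK_DOY = 197


def _daily_index(config: ClimateConfig) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{config.year_start}-01-01", f"{config.year_end}-12-31", freq="D"
    )


def _climatology(times: pd.DatetimeIndex, config: ClimateConfig) -> np.ndarray:
    # leap-day maps onto Feb 28 so the cycle is identical every calendar year
    doy = times.dayofyear.values.astype(float)
    leap = times.is_leap_year & (doy > 59)
    doy = doy - leap.astype(float)
    ang = 2.0 * np.pi * (doy - _PEAK_DOY) / 365.0
    return config.seasonal_mean + config.seasonal_amplitude * np.cos(ang)


def _ar1_noise(rng: np.random.Generator, n_cells: int, n_days: int, sd: float, phi: float) -> np.ndarray:
    """AR(1) noise with marginal standard deviation ``sd`` and lag-1 corr ``phi``."""
    if sd == 0.0:
        return np.zeros((n_cells, n_days))
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=(n_cells, n_days))
    # stationary start: x0 ~ N(0, sd^2)
    eps[:, 0] = rng.normal(0.0, sd, size=n_cells)
    return lfilter([1.0], [1.0, -phi], eps, axis=1)


def generate_temperature_grid(
    config: ClimateConfig, scenario: str = "observed", member: int = 0
) -> TemperatureGrid:
    """Generate one daily-tmax ensemble member for a scenario.

    The series is ``seasonal climatology + AR(1) noise + trend``, where the
    linear anthropogenic trend (``anthro_trend`` degC per decade, measured
    from the first day of the series) is added only for the observed and
    factual scenarios.  Counterfactual member *m* shares the noise
    realization of factual member *m*, so with ``anthro_trend=0`` the two are
    identical.  Deterministic given ``(config, scenario, member)``.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if not (0 <= member < config.n_members):
        raise ValueError(f"member {member} out of range [0, {config.n_members})")

    times = _daily_index(config)
    n_days = len(times)
    clim = _climatology(times, config)

    ss = np.random.SeedSequence([config.seed, _STREAM[scenario], member])
    rng = np.random.default_rng(ss)
    noise = _ar1_noise(rng, config.n_cells, n_days, config.noise_sd, config.noise_autocorr)

    values = clim[None, :] + noise
    if scenario in ("observed", "factual"):
        decades = (times - times[0]).days.values / 3652.5
        values = values + config.anthro_trend * decades[None, :]

    da = xr.DataArray(
        values,
        dims=("cell", "time"),
        coords={"cell": np.arange(config.n_cells), "time": times},
        name="tmax",
    )
    return TemperatureGrid(data=da, scenario=scenario, member=member)


def province_of_cell(config: ClimateConfig) -> pd.Series:
    """Contiguous partition of cells into provinces by index."""
    bounds = np.linspace(0, config.n_cells, config.n_provinces + 1).astype(int)
    prov = np.zeros(config.n_cells, dtype=int)
    for p in range(config.n_provinces):
        prov[bounds[p] : bounds[p + 1]] = p
    return pd.Series(prov, index=np.arange(config.n_cells), name="province")


def generate_demographics(
    config: ClimateConfig,
    base_ptb_rate: float = 0.07,
    ptb_growth: float = 1.013,
) -> DemographicTables:
    """Generate internally consistent demographic tables.

    PTB prevalence grows geometrically, ``rate[p, y] = base_p *
    ptb_growth**(y - y0)``, mirroring the observed ~1.3 %/yr national rise;
    monthly live-birth proportions are Dirichlet-distributed around uniform
    and normalized to sum to one.  Deterministic given ``config.seed``.
    """
    if not (0.0 < base_ptb_rate < 1.0):
        raise ValueError("base_ptb_rate must be in (0, 1)")
    years = list(config.years)
    horizon = len(years) - 1
    if base_ptb_rate * 1.1 * ptb_growth**horizon >= 1.0:
        raise ValueError("ptb_growth drives PTB rate to >= 1 within the year range")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    cells = np.arange(config.n_cells)
    provinces = np.arange(config.n_provinces)

    # population: ~100k persons per cell, deterministic 0.3 %/yr growth
    base_pop = rng.lognormal(mean=np.log(1e5), sigma=0.25, size=config.n_cells)
    growth = 1.003 ** np.arange(len(years))
    population = pd.DataFrame(
        np.round(base_pop[:, None] * growth[None, :]), index=cells, columns=years
    )

    # crude birth rate ~12 per 1000 person-years, constant per province
    br = np.clip(rng.normal(0.012, 0.0015, size=config.n_provinces), 0.006, 0.02)
    birth_rate = pd.DataFrame(
        np.repeat(br[:, None], len(years), axis=1), index=provinces, columns=years
    )

    base_p = base_ptb_rate * np.clip(rng.normal(1.0, 0.05, size=config.n_provinces), 0.9, 1.1)
    ptb = base_p[:, None] * ptb_growth ** np.arange(len(years))[None, :]
    if (ptb >= 1.0).any():
        raise ValueError("ptb_growth drives PTB rate to >= 1 within the year range")
    ptb_rate = pd.DataFrame(ptb, index=provinces, columns=years)

    props = rng.dirichlet(np.full(12, 60.0), size=config.n_provinces)
    props = props / props.sum(axis=1, keepdims=True)
    birth_month_prop = pd.DataFrame(props, index=provinces, columns=range(1, 13))

    return DemographicTables(
        population=population,
        birth_rate=birth_rate,
        ptb_rate=ptb_rate,
        birth_month_prop=birth_month_prop,
        province_of_cell=province_of_cell(config),
    )
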