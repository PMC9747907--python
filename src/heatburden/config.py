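"""Configuration objects for synthetic climate generation and pipeline runs."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

SCENARIOS = ("observed", "factual", "counterfactual")
#: Warm season months (May through October), when heatwave burden accrues.
DEFAULT_WARM_MONTHS = (5, 6, 7, 8, 9, 10)


@dataclass(frozen=True)
class ClimateConfig:
    """Parameters of the synthetic gridded daily-tmax generator.

    The generator emulates the statistical structure the attribution analysis
    relies on: a seasonal cycle, autocorrelated day-to-day weather noise, and
    a slow anthropogenic warming trend present only in the observed series and
    the factual ensemble.

    Parameters
    ----------
    n_cells : int
        Number of grid cells.
    n_provinces : int
        Number of provinces; cells are partitioned contiguously by index.
    year_start, year_end : int
        Inclusive year range of the daily series.
    seasonal_mean : float
        Annual-mean daily maximum temperature, degC.
    seasonal_amplitude : float
        Half peak-to-trough amplitude of the annual sinusoid, degC.
    noise_sd : float
        Marginal standard deviation of the AR(1) weather noise, degC.
    noise_autocorr : float
        Lag-1 autocorrelation of the noise, in [0, 1).
    anthro_trend : float
        Warming trend in degC per decade, added to observed and factual
        series only (measured from the first day of the series).
    n_members : int
        Ensemble size per simulated scenario.
    seed : int
        Master seed; all substreams derive from it deterministically.
    """

    n_cells: int = 8
    n_provinces: int = 2
    year_start: int = 2010
    year_end: int = 2020
    seasonal_mean: float = 18.0
    seasonal_amplitude: float = 12.0
    noise_sd: float = 3.0
    noise_autocorr: float = 0.7
    anthro_trend: float = 0.4
    n_members: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_provinces < 1 or self.n_cells < self.n_provinces:
            raise ValueError("need n_cells >= n_provinces >= 1")
        if not (0.0 <= self.noise_autocorr < 1.0):
            raise ValueError("noise_autocorr must be in [0, 1)")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClimateConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClimateConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Drives synthetic generation (or file inputs), heatwave definition,
    the exposure-response relationship, Monte Carlo uncertainty, and the
    human-capital stage from a single object.
    """

    climate: ClimateConfig = field(default_factory=ClimateConfig)
    analysis_years: Sequence[int] | None = None  # default: all data years
    warm_months: Sequence[int] = DEFAULT_WARM_MONTHS
    percentile: float = 0.90
    min_duration: int = 2
    window_days: int = 7
    rr: float = 1.19
    rr_ci: tuple[float, float] = (1.09, 1.29)
    n_draws: int = 1000
    base_ptb_rate: float = 0.07
    ptb_growth: float = 1.013
    outcome_spec_path: str | None = None  # None -> bundled synthetic fixture
    unit_cost_ptb: float = 0.070102  # million USD per preterm birth (direct cost)
    out_dir: str = "heatburden_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 1.0):
            raise ValueError("percentile must be in (0, 1)")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if not self.warm_months:
            raise ValueError("warm_months must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rr_ci"] = list(self.rr_ci)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "climate" in d and isinstance(d["climate"], dict):
            d["climate"] = ClimateConfig.from_dict(d["climate"])
        if "rr_ci" in d:
            d["rr_ci"] = tuple(d["rr_ci"])
        if "warm_months" in d:
            d["warm_months"] = tuple(d["warm_months"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
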