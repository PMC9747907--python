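"""Attributable preterm-birth accounting.

Baseline PTB counts follow the demographic product
``basePTB[g, m] = Pop[g, y] * BirthRate[g, y] * PTBrate[g, y] * BirthMon[g, m]``
for each warm-season month, spread evenly over that month's days.  On a day
whose mothers experienced at least one heatwave day in the final gestational
week, the attributable fraction is AF = (RR - 1)/RR; otherwise AF = 0.  The
attributable burden ``aPTB[g, d] = basePTB[g, d] * AF`` is summed to
provincial and national annual totals, and factual-minus-counterfactual
differences isolate the anthropogenic contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from heatburden.config import DEFAULT_WARM_MONTHS
from heatburden.containers import DemographicTables


@dataclass(frozen=True)
class RiskModel:
    """Relative risk of PTB given heatwave exposure in the last gestational
    week, with its 95% CI.  Default 1.19 (1.09-1.29)."""

    rr_point: float = 1.19
    rr_ci: tuple[float, float] = (1.09, 1.29)

    def __post_init__(self) -> None:
        if self.rr_point <= 0:
            raise ValueError("rr_point must be positive")
        lo, hi = self.rr_ci
        if not (0 < lo <= self.rr_point <= hi):
            raise ValueError("require 0 < ci_low <= rr_point <= ci_high")

    @property
    def af_point(self) -> float:
        return attributable_fraction(self.rr_point, True)


def attributable_fraction(rr: float | np.ndarray, exposed: bool | np.ndarray):
    """AF = (RR - 1)/RR among the exposed, 0 among the unexposed."""
    rr = np.asarray(rr, dtype=float)
    if (rr <= 0).any():
        raise ValueError("RR must be positive")
    af = (rr - 1.0) / rr
    out = np.where(np.asarray(exposed, dtype=bool), af, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class BaselinePTBField:
    """Expected baseline PTB counts on each warm-season cell-day.

    ``daily`` is a (cell, time) DataArray over the full daily index, zero on
    days outside warm-season months; ``monthly`` the cell x (year, month)
    table it derives from; the invariant ``daily * days_in_month == monthly``
    holds per cell-month.
    """

    daily: xr.DataArray
    monthly: pd.DataFrame  # index=cell, columns=MultiIndex (year, month)
    province_of_cell: pd.Series
    live_births: pd.DataFrame  # cell x year expected live births
    warm_months: tuple[int, ...] = DEFAULT_WARM_MONTHS

    def annual_baseline(self) -> pd.Series:
        """National warm-season baseline PTBs per year."""
        return self.monthly.T.groupby(level="year").sum().sum(axis=1)


def baseline_ptb(
    demo: DemographicTables,
    years: list[int] | None = None,
    warm_months: tuple[int, ...] = DEFAULT_WARM_MONTHS,
) -> BaselinePTBField:
    """Compute baseline PTB fields from demographic tables.

    Monthly values are the four-factor product of population, birth rate,
    PTB rate and monthly birth proportion (province values matched to every
    cell inside the province); daily values divide each month evenly over
    its calendar days.
    """
    years = list(years) if years is not None else demo.years
    missing = [y for y in years if y not in demo.years]
    if missing:
        raise ValueError(f"demographic tables do not cover years {missing}")
    cells = demo.population.index
    prov = demo.province_of_cell.loc[cells]
    if prov.isna().any():
        raise ValueError("cells without province data")

    cols = pd.MultiIndex.from_product([years, warm_months], names=["year", "month"])
    monthly = pd.DataFrame(0.0, index=cells, columns=cols)
    for y in years:
        pop = demo.population[y].values
        br = demo.birth_rate[y].loc[prov].values
        pr = demo.ptb_rate[y].loc[prov].values
        for m in warm_months:
            bm = demo.birth_month_prop[m].loc[prov].values
            monthly[(y, m)] = pop * br * pr * bm

    times = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    daily = np.zeros((len(cells), len(times)))
    ym = pd.Series(zip(times.year, times.month), index=times)
    days_in_month = times.days_in_month.values
    for j, (y, m) in enumerate(cols):
        sel = (times.year == y) & (times.month == m)
        if sel.any():
            daily[:, sel] = (monthly[(y, m)].values / days_in_month[sel][0])[:, None]
    da = xr.DataArray(
        daily,
        dims=("cell", "time"),
        coords={"cell": cells.values, "time": times},
        name="base_ptb",
    )
    lb = pd.DataFrame({y: demo.live_births(y) for y in years})
    return BaselinePTBField(
        daily=da,
        monthly=monthly,
        province_of_cell=prov,
        live_births=lb,
        warm_months=tuple(warm_months),
    )


@dataclass
class BurdenResult:
    """Attributable PTBs per cell-day with annual aggregations.

    ``national`` has one row per year with columns ``aptb`` (attributable
    PTBs), ``exposed_baseline`` (baseline PTBs on exposed warm-season days;
    aPTB for any RR is exposed_baseline * AF(RR)), ``baseline`` (all
    warm-season baseline PTBs), ``live_births``, ``per_million`` (aPTB per
    million live births) and ``share_pct`` (aPTB as % of warm-season
    baseline PTBs).
    """

    aptb_daily: xr.DataArray
    national: pd.DataFrame
    provincial: pd.DataFrame  # index=(province, year), columns aptb
    scenario: str = "observed"
    member: int = 0
    rr: float = 1.19

    @property
    def annual_total(self) -> pd.Series:
        return self.national["aptb"]

    @property
    def mean_annual(self) -> float:
        return float(self.national["aptb"].mean())

    def to_csv(self, path: str | Path) -> None:
        tab = self.national.reset_index().rename(columns={"index": "year"})
        tab.insert(0, "member", self.member)
        tab.insert(0, "scenario", self.scenario)
        tab.to_csv(path, index=False)


def attributable_ptb(
    base: BaselinePTBField,
    exposure: xr.DataArray,
    risk: RiskModel,
    scenario: str = "observed",
    member: int = 0,
) -> BurdenResult:
    """aPTB[g, d] = basePTB[g, d] * AF, aggregated to annual totals.

    Burden accrues only on warm-season days (the baseline field is zero
    elsewhere).  The per-million rate divides by annual national live
    births; the share divides by the annual warm-season baseline total.
    """
    if not np.array_equal(base.daily["cell"].values, exposure["cell"].values):
        raise ValueError("baseline field and exposure have different cells")
    if not np.array_equal(base.daily["time"].values, exposure["time"].values):
        raise ValueError("baseline field and exposure have different dates")

    af = risk.af_point
    exposed = exposure.values.astype(bool)
    base_vals = base.daily.values
    aptb_vals = base_vals * exposed * af
    aptb = xr.DataArray(
        aptb_vals, coords=base.daily.coords, dims=("cell", "time"), name="aptb"
    )

    times = pd.DatetimeIndex(base.daily["time"].values)
    years = times.year
    uyears = np.unique(years)
    nat_rows = []
    prov_rows = []
    prov = base.province_of_cell
    for y in uyears:
        sel = years == y
        aptb_y_cell = aptb_vals[:, sel].sum(axis=1)
        exposed_base_y = float((base_vals[:, sel] * exposed[:, sel]).sum())
        baseline_y = float(base_vals[:, sel].sum())
        lb_y = float(base.live_births[y].sum()) if y in base.live_births.columns else np.nan
        total = float(aptb_y_cell.sum())
        nat_rows.append(
            {
                "year": y,
                "aptb": total,
                "exposed_baseline": exposed_base_y,
                "baseline": baseline_y,
                "live_births": lb_y,
                "per_million": total / lb_y * 1e6 if lb_y > 0 else np.nan,
                "share_pct": total / baseline_y * 100.0 if baseline_y > 0 else np.nan,
            }
        )
        by_prov = pd.Series(aptb_y_cell, index=prov.index).groupby(prov.values).sum()
        for p, v in by_prov.items():
            prov_rows.append({"province": p, "year": y, "aptb": float(v)})

    national = pd.DataFrame(nat_rows).set_index("year")
    provincial = pd.DataFrame(prov_rows).set_index(["province", "year"])
    return BurdenResult(
        aptb_daily=aptb,
        national=national,
        provincial=provincial,
        scenario=scenario,
        member=member,
        rr=risk.rr_point,
    )


@dataclass
class ScenarioComparison:
    """Factual vs counterfactual ensembles and their difference.

    ``by_member_year`` holds per (member, year) factual, counterfactual and
    anthropogenic (= factual - counterfactual) attributable PTBs;
    ``ensemble`` averages over members per year, with the anthropogenic
    proportion computed on ensemble means of numerator and denominator.
    """

    by_member_year: pd.DataFrame
    ensemble: pd.DataFrame
    factual: list = field(default_factory=list, repr=False)
    counterfactual: list = field(default_factory=list, repr=False)

    @property
    def mean_annual_anthropogenic(self) -> float:
        return float(self.ensemble["anthropogenic"].mean())

    @property
    def mean_proportion_pct(self) -> float:
        num = self.ensemble["anthropogenic"].mean()
        den = self.ensemble["factual"].mean()
        return float(num / den * 100.0) if den > 0 else float("nan")


def scenario_difference(
    factual: list[BurdenResult], counterfactual: list[BurdenResult]
) -> ScenarioComparison:
    """Pair factual/counterfactual members and difference their burdens.

    Members are paired by climate-model index; the anthropogenic burden is
    the member-wise difference, and the annual proportion is ensemble-mean
    anthropogenic over ensemble-mean factual (missing where factual is 0).
    """
    f_members = {b.member: b for b in factual}
    c_members = {b.member: b for b in counterfactual}
    if set(f_members) != set(c_members):
        raise ValueError("factual and counterfactual ensembles have unpaired members")

    rows = []
    for m in sorted(f_members):
        fb, cb = f_members[m], c_members[m]
        if not fb.national.index.equals(cb.national.index):
            raise ValueError(f"member {m}: scenario years differ")
        for y in fb.national.index:
            f_v = fb.national.loc[y, "aptb"]
            c_v = cb.national.loc[y, "aptb"]
            rows.append(
                {
                    "member": m,
                    "year": y,
                    "factual": f_v,
                    "counterfactual": c_v,
                    "anthropogenic": f_v - c_v,
                }
            )
    bmy = pd.DataFrame(rows).set_index(["member", "year"])
    ens = bmy.groupby(level="year").mean()
    ens["proportion_pct"] = np.where(
        ens["factual"] > 0, ens["anthropogenic"] / ens["factual"] * 100.0, np.nan
    )
    return ScenarioComparison(
        by_member_year=bmy, ensemble=ens, factual=factual, counterfactual=counterfactual
    )
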