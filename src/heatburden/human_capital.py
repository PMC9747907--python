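"""Human-capital cascade: from attributable PTB counts to additional
outcome cases, lost IQ points, and monetized costs.

For a countable outcome, its relative risk given preterm birth,
``RR_outcome = I_e / I_0``, combines with the whole-population prevalence
``P_outcome = P_ptb * I_e + (1 - P_ptb) * I_e / RR_outcome`` to give the
incidence among preterm births,

    I_e = P_outcome * RR_outcome / (P_ptb * RR_outcome + 1 - P_ptb),

and the additional cases due to heatwave-related PTBs are
``N_add = nPTB * (I_e - P_outcome)``.  Reduced IQ is not countable: total
lost points are ``nPTB * iq_points_per_ptb``.  Costs multiply counts (or
points) by unit costs; neonatal death is excluded from the human-capital
total.  The model is exactly linear in nPTB, so CI bounds on the PTB count
pass through the same formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DIMENSIONS = ("health", "cognition", "non-cognition")


@dataclass(frozen=True)
class OutcomeSpec:
    """One downstream outcome of preterm birth.

    ``unit_cost`` is millions of USD per case (per IQ point for the
    non-countable reduced-IQ row), tagged with its currency year.
    """

    name: str
    dimension: str
    rr_outcome: float = 1.0
    p_outcome: float = 0.01
    unit_cost: float = 0.0
    currency_year: int = 2015
    include_in_total: bool = True
    countable: bool = True
    iq_points_per_ptb: float = 0.0

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {DIMENSIONS}")
        if self.countable:
            if self.rr_outcome <= 0:
                raise ValueError("rr_outcome must be positive")
            if not (0.0 < self.p_outcome < 1.0):
                raise ValueError("p_outcome must be in (0, 1)")
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be >= 0")


def incidence_in_ptb(spec: OutcomeSpec, p_ptb: float) -> tuple[float, float]:
    """Solve the prevalence identity for (I_e, I_0).

    Returns the outcome incidence among preterm (I_e) and non-preterm (I_0)
    births consistent with the population prevalence and RR_outcome.
    """
    if not (0.0 < p_ptb < 1.0):
        raise ValueError("p_ptb must be in (0, 1)")
    rr = spec.rr_outcome
    i_e = spec.p_outcome * rr / (p_ptb * rr + 1.0 - p_ptb)
    i_0 = i_e / rr
    if not (0.0 <= i_e <= 1.0):
        raise ValueError(
            f"inconsistent inputs for {spec.name}: implied I_e={i_e:.4g} outside [0, 1]"
        )
    return i_e, i_0


def additional_cases(nptb: float, spec: OutcomeSpec, p_ptb: float) -> float:
    """N_add = nPTB * (I_e - P_outcome)."""
    if nptb < 0:
        raise ValueError("nptb must be >= 0")
    i_e, _ = incidence_in_ptb(spec, p_ptb)
    return nptb * (i_e - spec.p_outcome)


def iq_loss(nptb: float, iq_points_per_ptb: float) -> float:
    """Total lost IQ points: points per preterm child times PTB count."""
    if nptb < 0 or iq_points_per_ptb < 0:
        raise ValueError("inputs must be >= 0")
    return nptb * iq_points_per_ptb


@dataclass
class HumanCapitalResult:
    """Table-shaped result: one row per outcome plus direct-PTB costs.

    ``table`` columns: name, dimension, n_add (cases or IQ points, with
    optional lo/hi from the PTB-count CI), unit_cost, currency_year, cost,
    include_in_total.  ``total_cost`` sums costs of included outcomes only
    (neonatal death excluded); ``direct_cost`` = nPTB * unit_cost_ptb.
    """

    nptb: float
    p_ptb: float
    table: pd.DataFrame
    direct_cost: float = np.nan
    total_cost: float = np.nan
    unit_cost_ptb: float = np.nan
    mixed_currency_years: bool = False
    nptb_ci: tuple[float, float] | None = None

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def compute_cases(
    nptb: float,
    specs: list[OutcomeSpec],
    p_ptb: float,
    nptb_ci: tuple[float, float] | None = None,
) -> HumanCapitalResult:
    """Additional cases / IQ points per outcome for an annual PTB count.

    CI bounds on nPTB, when given, are scaled through the same linear
    formulas to per-outcome bounds.
    """
    rows = []
    for spec in specs:
        if spec.countable:
            per_ptb = additional_cases(1.0, spec, p_ptb)
        else:
            per_ptb = spec.iq_points_per_ptb
        row = {
            "name": spec.name,
            "dimension": spec.dimension,
            "n_add": nptb * per_ptb,
            "unit_cost": spec.unit_cost,
            "currency_year": spec.currency_year,
            "include_in_total": spec.include_in_total,
        }
        if nptb_ci is not None:
            row["n_add_lo"] = nptb_ci[0] * per_ptb
            row["n_add_hi"] = nptb_ci[1] * per_ptb
        rows.append(row)
    return HumanCapitalResult(nptb=nptb, p_ptb=p_ptb, table=pd.DataFrame(rows), nptb_ci=nptb_ci)


def monetize(result: HumanCapitalResult, unit_cost_ptb: float) -> HumanCapitalResult:
    """Fill per-outcome costs, the direct aPTB cost and the human-capital total.

    Costs are unit cost times count (or IQ points); the total sums only
    outcomes flagged ``include_in_total``.  Sums mixing currency years are
    permitted but flagged.
    """
    if unit_cost_ptb < 0:
        raise ValueError("unit_cost_ptb must be >= 0")
    tab = result.table.copy()
    tab["cost"] = tab["n_add"] * tab["unit_cost"]
    included = tab[tab["include_in_total"]]
    result.table = tab
    result.direct_cost = result.nptb * unit_cost_ptb
    result.total_cost = float(included["cost"].sum())
    result.unit_cost_ptb = unit_cost_ptb
    result.mixed_currency_years = included["currency_year"].nunique() > 1
    return result


def load_outcome_specs(path: str | Path) -> list[OutcomeSpec]:
    """Read an outcome panel from CSV (see ``default_outcome_specs``)."""
    df = pd.read_csv(path)
    specs = []
    for _, r in df.iterrows():
        specs.append(
            OutcomeSpec(
                name=r["name"],
                dimension=r["dimension"],
                rr_outcome=float(r.get("rr_outcome", 1.0)),
                p_outcome=float(r.get("p_outcome", 0.01)),
                unit_cost=float(r["unit_cost"]),
                currency_year=int(r["currency_year"]),
                include_in_total=bool(r["include_in_total"]),
                countable=bool(r["countable"]),
                iq_points_per_ptb=float(r.get("iq_points_per_ptb", 0.0)),
            )
        )
    return specs


def save_outcome_specs(specs: list[OutcomeSpec], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in specs]).to_csv(path, index=False)


def default_outcome_specs() -> list[OutcomeSpec]:
    """The bundled synthetic outcome panel.

    Shipped as an editable CSV fixture; RRs and prevalences are synthetic
    placeholders, while unit costs and IQ points per PTB are the values a
    published aggregate cost table implies.
    """
    with resources.as_file(
        resources.files("heatburden.data").joinpath("human_capital_outcomes_synthetic.csv")
    ) as p:
        return load_outcome_specs(p)
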