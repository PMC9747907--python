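"""End-to-end orchestration: synthetic inputs -> detection -> bias
correction -> burden -> uncertainty -> human capital, from one RunConfig.

Stage outputs are plain CSV/NetCDF files in the output directory so stages
can be rerun independently; a JSON manifest records the config hash, seed
and package version.  The run is deterministic given config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from heatburden.bias_correction import apply_bias_correction, fit_bias_correction
from heatburden.burden import (
    RiskModel,
    attributable_ptb,
    baseline_ptb,
    scenario_difference,
)
from heatburden.config import RunConfig
from heatburden.containers import DemographicTables
from heatburden.heatwave import HeatwaveDetector, exposure_window, heatwave_days_by_year
from heatburden.human_capital import compute_cases, default_outcome_specs, load_outcome_specs, monetize
from heatburden.synthetic import generate_demographics, generate_temperature_grid
from heatburden.uncertainty import MonteCarloSpec, burden_ci, comparison_ci

log = logging.getLogger("heatburden")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def national_ptb_rate(demo: DemographicTables, years: list[int]) -> float:
    """Live-birth-weighted national PTB rate averaged over years."""
    vals = []
    for y in years:
        lb = demo.live_births(y)
        prov = demo.province_of_cell.loc[lb.index]
        rate = demo.ptb_rate[y].loc[prov].values
        vals.append(float((lb.values * rate).sum() / lb.values.sum()))
    return float(np.mean(vals))


def _burden_for_grid(grid, detector, base, risk):
    mask = detector.transform(grid)
    exposed = exposure_window(mask, detector.window_days)
    exposed = exposed.sel(time=base.daily["time"])
    return attributable_ptb(base, exposed, risk, scenario=grid.scenario, member=grid.member), mask


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage and write output tables; returns the result bundle.

    The returned dict holds the in-memory results (burden tables, scenario
    comparison, CIs, human-capital tables) plus the manifest written to
    ``out_dir``.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cc = config.climate
    years = list(config.analysis_years) if config.analysis_years else list(cc.years)

    log.info("stage synthetic: %d cells, %d provinces, years %d-%d, %d members",
             cc.n_cells, cc.n_provinces, cc.year_start, cc.year_end, cc.n_members)
    observed = generate_temperature_grid(cc, "observed", 0)
    demo = generate_demographics(cc, config.base_ptb_rate, config.ptb_growth)
    demo.to_csv(out / "demographics")

    risk = RiskModel(rr_point=config.rr, rr_ci=tuple(config.rr_ci))
    mc = MonteCarloSpec(n_draws=config.n_draws, seed=config.seed)

    detector = HeatwaveDetector(
        config.percentile, tuple(config.warm_months), config.min_duration, config.window_days
    ).fit(observed)
    base = baseline_ptb(demo, years, tuple(config.warm_months))

    obs_burden, obs_mask = _burden_for_grid(observed, detector, base, risk)
    heatwave_days_by_year(obs_mask).to_csv(out / "heatwave_days_observed.csv")
    obs_burden.to_csv(out / "burden_observed.csv")
    log.info("stage observed burden: mean annual aPTB %.3f over %d cell-days",
             obs_burden.mean_annual, obs_burden.aptb_daily.size)

    factual_burdens, counterfactual_burdens = [], []
    for m in range(cc.n_members):
        fact = generate_temperature_grid(cc, "factual", m)
        ctf = generate_temperature_grid(cc, "counterfactual", m)
        mapper = fit_bias_correction(fact, observed)
        fact_bc = apply_bias_correction(fact, mapper)
        ctf_bc = apply_bias_correction(ctf, mapper)
        # thresholds per model from the bias-corrected factual run, applied
        # unchanged to the counterfactual so the attribution signal survives
        det_m = HeatwaveDetector(
            config.percentile, tuple(config.warm_months), config.min_duration, config.window_days
        ).fit(fact_bc)
        fb, _ = _burden_for_grid(fact_bc, det_m, base, risk)
        cb, _ = _burden_for_grid(ctf_bc, det_m, base, risk)
        factual_burdens.append(fb)
        counterfactual_burdens.append(cb)
    pd.concat([b.national.assign(member=b.member) for b in factual_burdens]).to_csv(
        out / "burden_factual.csv"
    )
    pd.concat([b.national.assign(member=b.member) for b in counterfactual_burdens]).to_csv(
        out / "burden_counterfactual.csv"
    )

    comp = scenario_difference(factual_burdens, counterfactual_burdens)
    comp.ensemble.to_csv(out / "anthropogenic.csv")
    log.info("stage scenarios: mean annual anthropogenic aPTB %.3f (%.1f%% of factual)",
             comp.mean_annual_anthropogenic, comp.mean_proportion_pct)

    obs_ci = burden_ci(obs_burden, risk, mc)
    scen_ci = comparison_ci(comp, risk, mc)
    ci_rows = [
        {"quantity": "observed_aptb", **{k: obs_ci[k] for k in ("point", "lo", "hi", "n_draws", "n_models", "seed")}},
        {"quantity": "anthropogenic_aptb", "point": scen_ci["anthropogenic"]["point"],
         "lo": scen_ci["anthropogenic"]["lo"], "hi": scen_ci["anthropogenic"]["hi"],
         "n_draws": scen_ci["n_draws"], "n_models": scen_ci["n_models"], "seed": scen_ci["seed"]},
        {"quantity": "anthropogenic_proportion_pct", "point": scen_ci["proportion_pct"]["point"],
         "lo": scen_ci["proportion_pct"]["lo"], "hi": scen_ci["proportion_pct"]["hi"],
         "n_draws": scen_ci["n_draws"], "n_models": scen_ci["n_models"], "seed": scen_ci["seed"]},
    ]
    pd.DataFrame(ci_rows).to_csv(out / "confidence_intervals.csv", index=False)

    specs = (
        load_outcome_specs(config.outcome_spec_path)
        if config.outcome_spec_path
        else default_outcome_specs()
    )
    p_ptb = national_ptb_rate(demo, years)
    unit_cost_ptb = config.unit_cost_ptb
    hc_obs = monetize(
        compute_cases(obs_burden.mean_annual, specs, p_ptb, (obs_ci["lo"], obs_ci["hi"])),
        unit_cost_ptb,
    )
    hc_anthro = monetize(
        compute_cases(
            max(comp.mean_annual_anthropogenic, 0.0),
            specs,
            p_ptb,
            (scen_ci["anthropogenic"]["lo"], scen_ci["anthropogenic"]["hi"]),
        ),
        unit_cost_ptb,
    )
    hc_obs.to_csv(out / "human_capital_observed.csv")
    hc_anthro.to_csv(out / "human_capital_anthropogenic.csv")

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": _package_version(),
        "analysis_years": years,
        "n_members": cc.n_members,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "observed": obs_burden,
        "factual": factual_burdens,
        "counterfactual": counterfactual_burdens,
        "comparison": comp,
        "observed_ci": obs_ci,
        "scenario_ci": scen_ci,
        "human_capital_observed": hc_obs,
        "human_capital_anthropogenic": hc_anthro,
        "p_ptb": p_ptb,
        "demographics": demo,
        "manifest": manifest,
    }


def _package_version() -> str:
    import heatburden

    return heatburden.__version__
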