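"""Monte Carlo uncertainty propagation for attributable burdens.

The dominant uncertainty is the exposure-response relationship: the log
relative risk is treated as normal with mean ln(RR_point) and standard
deviation recovered from the printed 95% CI, sd = (ln hi - ln lo)/(2 z),
z = 1.959964.  One RR draw applies to every cell and day of a replicate
(the RR is a single national parameter).  Because the attributable burden
is linear in AF, each draw's burden is exposed_baseline * AF(draw), so
propagation is exact and cheap.  For scenario estimates the empirical 95%
CI flattens draws across climate-model members as well; for observed-
climate estimates it uses draws only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from heatburden.burden import BurdenResult, RiskModel, ScenarioComparison, attributable_fraction

Z95 = 1.959964


@dataclass(frozen=True)
class MonteCarloSpec:
    """Monte Carlo settings: number of coefficient draws and the seed."""

    n_draws: int = 1000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")


def sd_log_rr(risk: RiskModel) -> float:
    """Standard deviation of ln RR implied by the 95% CI."""
    lo, hi = risk.rr_ci
    return (np.log(hi) - np.log(lo)) / (2.0 * Z95)


def sample_rr(risk: RiskModel, spec: MonteCarloSpec) -> np.ndarray:
    """Draw RR samples: exp(Normal(ln rr_point, sd)); deterministic per seed."""
    lo, hi = risk.rr_ci
    if not (0 < lo <= risk.rr_point <= hi):
        raise ValueError("invalid CI ordering")
    sd = sd_log_rr(risk)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    return np.exp(rng.normal(np.log(risk.rr_point), sd, size=spec.n_draws))


def empirical_ci(estimates: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval of the flattened empirical distribution.

    For the default level this is the 2.5th/97.5th percentile pair, with
    linear interpolation between order statistics.
    """
    arr = np.asarray(estimates, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty estimate vector")
    if arr.size < 2:
        raise ValueError("need at least 2 estimates for an empirical CI")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def _mean_annual_exposed_baseline(result: BurdenResult) -> float:
    return float(result.national["exposed_baseline"].mean())


def burden_ci(
    results: BurdenResult | list[BurdenResult],
    risk: RiskModel,
    spec: MonteCarloSpec,
) -> dict:
    """CI of the mean annual attributable PTB count.

    A single observed-climate result yields a draws-only CI; a list of
    ensemble members yields a CI over the flattened draws x members
    distribution, capturing both RR imprecision and climate-model spread.
    """
    draws = sample_rr(risk, spec)
    af = attributable_fraction(draws, True)
    if isinstance(results, BurdenResult):
        base = _mean_annual_exposed_baseline(results)
        est = base * af
        n_models = 1
    else:
        bases = np.array([_mean_annual_exposed_baseline(r) for r in results])
        est = np.outer(af, bases)  # draws x members
        n_models = len(results)
    lo, hi = empirical_ci(est, spec.level)
    point = (
        _mean_annual_exposed_baseline(results) * risk.af_point
        if isinstance(results, BurdenResult)
        else float(np.mean([_mean_annual_exposed_baseline(r) for r in results]) * risk.af_point)
    )
    return {
        "point": point,
        "lo": lo,
        "hi": hi,
        "n_draws": spec.n_draws,
        "n_models": n_models,
        "seed": spec.seed,
    }


def comparison_ci(comp: ScenarioComparison, risk: RiskModel, spec: MonteCarloSpec) -> dict:
    """CIs for the anthropogenic burden and its proportion of the factual.

    Per member, mean annual anthropogenic burden for an RR draw is
    (factual - counterfactual exposed baseline) * AF(draw); the proportion
    AF cancels, so its spread reflects climate-model variability alone.
    """
    draws = sample_rr(risk, spec)
    af = attributable_fraction(draws, True)
    f_base = np.array([_mean_annual_exposed_baseline(r) for r in comp.factual])
    c_base = np.array([_mean_annual_exposed_baseline(r) for r in comp.counterfactual])
    anthro = np.outer(af, f_base - c_base)
    lo, hi = empirical_ci(anthro, spec.level)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(f_base > 0, (f_base - c_base) / f_base * 100.0, np.nan)
    prop = prop[np.isfinite(prop)]
    plo, phi = empirical_ci(prop, spec.level) if prop.size >= 2 else (np.nan, np.nan)
    return {
        "anthropogenic": {
            "point": float((f_base - c_base).mean() * risk.af_point),
            "lo": lo,
            "hi": hi,
        },
        "proportion_pct": {
            "point": comp.mean_proportion_pct,
            "lo": float(plo),
            "hi": float(phi),
        },
        "n_draws": spec.n_draws,
        "n_models": len(f_base),
        "seed": spec.seed,
    }
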