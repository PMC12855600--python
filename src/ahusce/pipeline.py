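"""End-to-end orchestration: one function call from inputs to outcomes.

This is the layer everything else (scenarios, sensitivity analyses, the
command line) builds on: given a parameter set, a life table and a fitted
relapse model, it runs both strategy arms deterministically and returns the
incremental comparison.
"""

from __future__ import annotations

import numpy as np

from . import econ, survival
from .cohort import (
    LifeTable,
    build_transition_matrices,
    discount_factors,
    discounted_life_years,
    initial_distribution,
    load_reference_life_table,
    run_cohort,
)
from .params import ModelConfig, ParameterSet, load_parameters

__all__ = ["run_arm", "run_model", "base_case_inputs", "reference_relapse_fit"]


def reference_relapse_fit(data: survival.SurvivalData | None = None) -> survival.SurvivalFit:
    """Base-case relapse curve: lognormal override on the fixture fits."""
    data = data or survival.load_reference_relapse_data()
    fits = survival.fit_all(data)
    return survival.select_model(fits, policy="named_override", override="lognormal")


def base_case_inputs(
    params: ParameterSet | None = None,
    table: LifeTable | None = None,
    relapse_fit: survival.SurvivalFit | None = None,
):
    """Bundled defaults for (params, life table, relapse fit)."""
    params = params or load_parameters()
    table = table or load_reference_life_table()
    relapse_fit = relapse_fit or reference_relapse_fit()
    return params, table, relapse_fit


def run_arm(
    arm: str,
    values: dict[str, float],
    config: ModelConfig,
    table: LifeTable,
    relapse_probs: np.ndarray,
    drug: str = "eculizumab",
    price_multiplier: float = 1.0,
) -> econ.ArmOutcomes:
    """Run one strategy arm at fixed parameter values."""
    matrices = build_transition_matrices(arm, values, relapse_probs, table, config)
    trace = run_cohort(initial_distribution(arm, values), arm, values,
                       relapse_probs, table, config, matrices=matrices)
    payoffs = econ.cost_matrix(values, config, arm, drug=drug,
                               price_multiplier=price_multiplier)
    qaly, cost = econ.accumulate(trace, payoffs, config, matrices=matrices)
    ly = discounted_life_years(trace, config)
    breakdown = _cost_breakdown(trace, payoffs, config, matrices)
    return econ.ArmOutcomes(arm=arm, life_years=ly, qalys=qaly, cost=cost,
                            cost_breakdown=breakdown)


def _cost_breakdown(trace, payoffs, config, matrices) -> dict[str, float]:
    from .cohort import cycle_occupancy

    occ = cycle_occupancy(trace, config)
    disc = discount_factors(config, occ.shape[0])
    out = {
        k: float(np.einsum("ts,ts,t->", occ, v, disc))
        for k, v in payoffs.cost_components.items()
    }
    out["transplant"] = out.get("transplant", 0.0) + float(
        np.sum(econ.transplant_inflow(trace) * disc) * payoffs.transplant_oneoff
    )
    if payoffs.induction_oneoff:
        inc = econ.relapse_incidence(trace, matrices)
        out["drug"] += float(np.sum(inc * disc) * payoffs.induction_oneoff)
    return out


def run_model(
    params: ParameterSet | None = None,
    table: LifeTable | None = None,
    relapse_fit: survival.SurvivalFit | None = None,
    values: dict[str, float] | None = None,
    drug: str = "eculizumab",
    price_multiplier: float = 1.0,
) -> econ.EconomicOutcomes:
    """Deterministic two-arm comparison.

    ``values`` overrides the point evaluation (used by the PSA, which passes
    a sampled value dictionary).
    """
    params, table, relapse_fit = base_case_inputs(params, table, relapse_fit)
    config = params.config
    vals = values if values is not None else params.point_values()
    relapse_probs = survival.cycle_probabilities(relapse_fit, config)
    w = run_arm("withdrawal", vals, config, table, relapse_probs, drug, price_multiplier)
    m = run_arm("maintenance", vals, config, table, relapse_probs, drug, price_multiplier)
    return econ.incremental(w, m, wtp_grid=config.wtp_grid)
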