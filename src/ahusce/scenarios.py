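"""Published scenario analyses as named variants of the base-case pipeline.

Each scenario is a :class:`ScenarioSpec` — parameter overrides, a survival
family override, a horizon or drug change, a price multiplier, or the
alternative multiple-withdrawal strategy — run through the same engine as
the base case.  :func:`scenario_suite` reproduces the full published
scenario table (eleven rows, base case included).

The multiple-withdrawal strategy is semi-Markov: relapse risk depends on
time since the *current* withdrawal, so the off-treatment states are
expanded by a within-episode clock.  Patients who relapse receive a fixed
three-month re-treatment course and then withdraw again with the relapse
clock reset; relapses that progress beyond CKD 3 stay on treatment for
life.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import econ, survival
from .cohort import LifeTable, cycle_death_probabilities, discount_factors
from .econ import ArmOutcomes, EconomicOutcomes
from .params import ModelConfig, ParameterSet
from .pipeline import run_arm, run_model

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "run_scenario",
    "multiple_withdrawal_model",
    "scenario_suite",
    "COURSE_CYCLES",
]

#: re-treatment course length: three 365.25/12-day months in 14-day cycles
COURSE_CYCLES = int(np.ceil(3 * (365.25 / 12) / 14))

#: guard against runaway phase expansion (cells = cycles x phases)
MAX_PHASE_CELLS = 10_000_000


@dataclass
class ScenarioSpec:
    """A named, declarative variant of the base-case analysis."""

    name: str
    description: str = ""
    overrides: dict[str, float] = field(default_factory=dict)
    survival_family: str | None = None  # None = base-case lognormal override
    horizon_years: float | None = None  # horizon from model start, in years
    strategy: str = "single_withdrawal"  # or "multiple_withdrawal"
    drug: str = "eculizumab"
    price_multiplier: float = 1.0


SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in (
        ScenarioSpec("base_case", "Deterministic base case"),
        ScenarioSpec(
            "multiple_withdrawals",
            "Relapse triggers a 3-month re-treatment course, then withdrawal again",
            strategy="multiple_withdrawal",
        ),
        ScenarioSpec(
            "gompertz_restart",
            "Favourable (plateauing) relapse extrapolation",
            survival_family="gompertz",
        ),
        ScenarioSpec(
            "exponential_restart",
            "Unfavourable (constant-hazard) relapse extrapolation",
            survival_family="exponential",
        ),
        ScenarioSpec(
            "literature_utilities",
            "CKD 0-3 baseline utility from published literature values "
            "(labelled assumption: override chosen to lift arm QALYs by ~3)",
            overrides={"utility_baseline_ckd03": 0.99},
        ),
        ScenarioSpec(
            "outlier_controlled_utilities",
            "Trial utility estimates after controlling for the extreme outlier "
            "(labelled assumption)",
            overrides={
                "utility_baseline_ckd03": 0.88,
                "utility_withdrawal_increment": 0.016,
            },
        ),
        ScenarioSpec(
            "outlier_controlled_costs",
            "Trial direct-cost estimates after controlling for the extreme "
            "outlier (labelled assumption)",
            overrides={"cost_management_withdrawal": -15.0},
        ),
        ScenarioSpec("ravulizumab", "Ravulizumab replaces eculizumab", drug="ravulizumab"),
        ScenarioSpec("horizon_2y", "2-year time horizon", horizon_years=2.0),
        ScenarioSpec("horizon_10y", "10-year time horizon", horizon_years=10.0),
        ScenarioSpec(
            "price_reduction_50", "50% eculizumab price reduction", price_multiplier=0.5
        ),
    )
}


def _resolve_fit(
    spec: ScenarioSpec, fits: dict[str, survival.SurvivalFit]
) -> survival.SurvivalFit:
    if spec.survival_family is None:
        return survival.select_model(fits, policy="named_override", override="lognormal")
    if spec.survival_family not in fits:
        raise ValueError(f"no fitted {spec.survival_family!r} model available")
    return fits[spec.survival_family]


def run_scenario(
    spec: ScenarioSpec | str,
    params: ParameterSet | None = None,
    table: LifeTable | None = None,
    fits: dict[str, survival.SurvivalFit] | None = None,
) -> EconomicOutcomes:
    """Run one named scenario and return its incremental outcomes."""
    if isinstance(spec, str):
        if spec not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {spec!r}; available: {', '.join(sorted(SCENARIOS))}"
            )
        spec = SCENARIOS[spec]
    if params is None or table is None:
        from .cohort import load_reference_life_table
        from .params import load_parameters

        params = params or load_parameters()
        table = table or load_reference_life_table()
    if fits is None:
        fits = survival.fit_all(survival.load_reference_relapse_data())
    fit = _resolve_fit(spec, fits)

    if spec.overrides:
        params = params.with_overrides(**spec.overrides)
    if spec.horizon_years is not None:
        params = params.with_config(
            horizon_age=params.config.starting_age + spec.horizon_years
        )

    if spec.strategy == "multiple_withdrawal":
        withdrawal = multiple_withdrawal_model(params, fit, table,
                                               drug=spec.drug,
                                               price_multiplier=spec.price_multiplier)
        config = params.config
        relapse_probs = survival.cycle_probabilities(fit, config)
        maintenance = run_arm("maintenance", params.point_values(), config, table,
                              relapse_probs, drug=spec.drug,
                              price_multiplier=spec.price_multiplier)
        return econ.incremental(withdrawal, maintenance, wtp_grid=config.wtp_grid)

    return run_model(params, table, fit, drug=spec.drug,
                     price_multiplier=spec.price_multiplier)


def scenario_suite(
    params: ParameterSet | None = None,
    table: LifeTable | None = None,
    fits: dict[str, survival.SurvivalFit] | None = None,
) -> pd.DataFrame:
    """All published scenarios as one table (one row per scenario)."""
    if fits is None:
        fits = survival.fit_all(survival.load_reference_relapse_data())
    rows = []
    for name, spec in SCENARIOS.items():
        out = run_scenario(spec, params, table, fits)
        rows.append({"scenario": name, "description": spec.description}
                    | out.summary_row())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiple-withdrawal (semi-Markov) strategy
# ---------------------------------------------------------------------------

# valuation classes for the phase-expanded model
_CLASSES = (
    "off_month1", "off_months2_8", "off_month8plus",
    "course", "ckd4", "esrd", "transplant", "post_tx", "dead",
)


def multiple_withdrawal_model(
    params: ParameterSet,
    relapse_fit: survival.SurvivalFit,
    table: LifeTable,
    course_cycles: int = COURSE_CYCLES,
    drug: str = "eculizumab",
    price_multiplier: float = 1.0,
    values: dict[str, float] | None = None,
    return_aggregates: bool = False,
):
    """Expected-value cohort model of the repeated-withdrawal strategy.

    The off-treatment states carry a within-episode clock (cycles since the
    current withdrawal) so the relapse hazard and the phased monitoring
    costs restart after every re-treatment course.  On-treatment cycles
    carry no progression risk; relapses that present beyond CKD 3 remain on
    treatment for life and follow the advanced-disease chain.
    """
    config = params.config
    vals = values if values is not None else params.point_values()
    n = config.n_cycles
    if (n + 1) * (n + 1) > MAX_PHASE_CELLS:
        raise MemoryError(
            "phase expansion exceeds the memory guard; use a coarser horizon"
        )
    p_die = cycle_death_probabilities(config, table, n)
    # relapse probability indexed by within-episode phase (padded one slot)
    p_rel_all = survival.cycle_probabilities(relapse_fit, config)
    p_rel_all = np.append(p_rel_all, p_rel_all[-1])

    prog02, prog3 = vals["relapse_progression_ckd02"], vals["relapse_progression_ckd3"]
    p45, p5t = vals["ckd4_to_esrd"], vals["esrd_to_transplant"]
    if config.advanced_progression_annual:
        p45 = 1 - (1 - p45) ** (1 / config.cycles_per_year)
        p5t = 1 - (1 - p5t) ** (1 / config.cycles_per_year)
    pfail = vals["transplant_failure"]
    exc = {k: vals[f"excess_mortality_{k}"] for k in ("esrd", "transplant", "post_transplant")}

    # phase-resolved off-treatment masses (one slot per cycles-since-withdrawal)
    off02 = np.zeros(n + 2)
    off3 = np.zeros(n + 2)
    off02[0] = vals["pct_ckd02"]
    off3[0] = 1 - vals["pct_ckd02"]
    course02 = np.zeros(course_cycles + 1)  # index = remaining course cycles
    course3 = np.zeros(course_cycles + 1)
    ckd4 = esrd = trans = post = dead = 0.0

    month_days = 365.25 / 12
    # phase p ends (p+1) cycles into the episode; same banding as the
    # single-withdrawal monitoring schedule
    phase_end = (np.arange(n + 2) + 1) * config.cycle_length_days / month_days
    band0 = phase_end <= 1.0 + 1e-9
    band1 = ~band0 & (phase_end <= 8.0 + 1e-9)
    band2 = ~band0 & ~band1

    cls = np.zeros((n + 1, len(_CLASSES)))
    relapses = np.zeros(n)
    transplants = np.zeros(n)

    def record(t):
        off = off02 + off3
        cls[t] = (
            off[band0].sum(), off[band1].sum(), off[band2].sum(),
            course02.sum() + course3.sum(), ckd4, esrd, trans, post, dead,
        )

    record(0)
    for t in range(n):
        d = p_die[t]
        de = min(d + exc["esrd"], 1.0)
        dt_ = min(d + exc["transplant"], 1.0)
        dp = min(d + exc["post_transplant"], 1.0)

        surv02 = off02[: n + 1] * (1 - d)
        surv3 = off3[: n + 1] * (1 - d)
        rel02 = surv02 * p_rel_all[: n + 1]
        rel3 = surv3 * p_rel_all[: n + 1]
        dead += (off02.sum() + off3.sum()) * d
        new_off02 = np.zeros(n + 2)
        new_off3 = np.zeros(n + 2)
        new_off02[1:] = surv02 - rel02
        new_off3[1:] = surv3 - rel3
        r02, r3 = rel02.sum(), rel3.sum()
        relapses[t] = r02 + r3

        # course bookkeeping: survivors shift down one remaining-cycle slot
        dead += (course02.sum() + course3.sum()) * d
        sc02 = course02 * (1 - d)
        sc3 = course3 * (1 - d)
        finished02, finished3 = sc02[1], sc3[1]
        new_c02 = np.zeros(course_cycles + 1)
        new_c3 = np.zeros(course_cycles + 1)
        new_c02[1:course_cycles] = sc02[2 : course_cycles + 1]
        new_c3[1:course_cycles] = sc3[2 : course_cycles + 1]
        new_c02[course_cycles] = r02 * (1 - prog02)
        new_c3[course_cycles] = r02 * prog02 + r3 * (1 - prog3)
        new_off02[0] = finished02
        new_off3[0] = finished3

        # advanced-disease chain (same rules as the single-withdrawal engine)
        dead += ckd4 * d + esrd * de + trans * dt_ + post * dp
        new_ckd4 = ckd4 * (1 - d) * (1 - p45) + r3 * prog3
        new_esrd = esrd * (1 - de) * (1 - p5t) + ckd4 * (1 - d) * p45 + trans * (1 - dt_) * pfail
        new_trans = esrd * (1 - de) * p5t
        transplants[t] = new_trans
        new_post = post * (1 - dp) + trans * (1 - dt_) * (1 - pfail)

        off02, off3 = new_off02, new_off3
        course02, course3 = new_c02, new_c3
        ckd4, esrd, trans, post = new_ckd4, new_esrd, new_trans, new_post
        record(t + 1)

    total = cls.sum(axis=1)
    if not np.allclose(total, 1.0, atol=1e-9):
        raise RuntimeError("multiple-withdrawal masses do not conserve")

    outcomes = _value_multiple_withdrawal(
        cls, relapses, transplants, vals, config, drug, price_multiplier
    )
    if return_aggregates:
        return outcomes, {
            "class_occupancy": cls,
            "classes": _CLASSES,
            "relapses": relapses,
            "transplants": transplants,
        }
    return outcomes


def _value_multiple_withdrawal(
    cls: np.ndarray,
    relapses: np.ndarray,
    transplants: np.ndarray,
    vals: dict[str, float],
    config: ModelConfig,
    drug: str,
    price_multiplier: float,
) -> ArmOutcomes:
    """Attach utilities and costs to the class-occupancy trace."""
    n = cls.shape[0] - 1
    occ = 0.5 * (cls[:-1] + cls[1:]) if config.half_cycle_correction else cls[:-1]
    disc = discount_factors(config, n)
    dy = config.cycle_years

    base = vals["utility_baseline_ckd03"]
    u_class = np.array([
        base + vals["utility_withdrawal_increment"],
        base + vals["utility_withdrawal_increment"],
        base + vals["utility_withdrawal_increment"],
        base,  # on a re-treatment course
        base + vals["disutility_ckd4"],
        base + vals["disutility_esrd"],
        vals["utility_transplant_procedure"],
        base + vals["disutility_post_transplant"],
        0.0,
    ])
    offset = 0.5 if config.half_cycle_correction else 0.0
    ages = config.starting_age + (np.arange(n) + offset) * dy
    if config.utility_age_adjustment:
        g = econ.age_utility_factor(ages, config.male_fraction) / econ.age_utility_factor(
            config.starting_age, config.male_fraction
        )
    else:
        g = np.ones(n)
    util = np.clip(np.outer(g, u_class), -1.0, 1.0)
    qaly = float(np.einsum("ts,ts,t->", occ, util, disc) * dy)
    if config.relapse_disutility_mode == "transient":
        qaly += float(np.sum(relapses * disc) * vals["utility_relapse_decrement"] * dy)

    spec = econ.DRUGS[drug]
    vial = vals[f"cost_{drug}_vial"] * price_multiplier
    drug_cycle = spec["vials_per_cycle"] * vial
    delivery = (1 - vals["pct_home_delivery"]) * vals["cost_hospital_delivery"] \
        * spec["deliveries_per_cycle"]
    on_tx = drug_cycle + delivery + vals["cost_antibiotics"] + vals["cost_monitoring_maintenance"]
    c_class = np.array([
        vals["cost_monitoring_withdrawal_month1"] + vals["cost_management_withdrawal"],
        vals["cost_monitoring_withdrawal_months2_8"] + vals["cost_management_withdrawal"],
        vals["cost_monitoring_withdrawal_month8plus"] + vals["cost_management_withdrawal"],
        on_tx + vals["cost_management_relapse"],
        on_tx + vals["cost_management_ckd4"],
        on_tx + vals["cost_management_esrd"],
        on_tx,
        on_tx + vals["cost_management_post_transplant"],
        0.0,
    ])
    cost = float(np.einsum("ts,s,t->", occ, c_class, disc))
    induction = spec["induction_extra_vials"] * vial
    cost += float(np.sum(relapses * disc) * induction)
    cost += float(np.sum(transplants * disc) * vals["cost_transplant"])

    alive = 1.0 - occ[:, -1]
    ly = float(np.sum(alive * disc) * dy)
    return ArmOutcomes(arm="multiple_withdrawal", life_years=ly, qalys=qaly, cost=cost)
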