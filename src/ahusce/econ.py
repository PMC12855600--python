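"""State payoffs and incremental cost-effectiveness measures.

Utilities: patients at CKD 0-3 carry the trial baseline utility (0.86),
with a small increment while off treatment and a decrement at relapse;
advanced disease applies published disutilities and the transplant
procedure cycle an absolute utility.  All state utilities decline with age
along a general-population quadratic normalised to 1 at the starting age.

Costs: on-treatment states accrue drug acquisition, nurse delivery (hospital
deliveries only — homecare delivery is funded by the manufacturer),
prophylactic antibiotics and maintenance monitoring; off-treatment states
accrue the phased withdrawal-monitoring schedule and a management offset.
Transplant surgery and post-relapse treatment re-initiation are one-off
costs attached to incident transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    IDX,
    N_STATES,
    STATES,
    CohortTrace,
    cycle_occupancy,
    discount_factors,
)
from .params import ModelConfig

__all__ = [
    "PayoffSchedule",
    "ArmOutcomes",
    "EconomicOutcomes",
    "age_utility_factor",
    "state_utilities",
    "utility_matrix",
    "state_costs",
    "cost_matrix",
    "accumulate",
    "incremental",
    "DRUGS",
]

# general-population EQ-5D age profile (quadratic in age with a sex shift),
# used only as a relative decline normalised to the starting age
_AGE_COEF = dict(const=0.9508566, male=0.0212126, age=-0.0002587, age2=-0.0000332)

#: per-drug dosing: vials per 2-week cycle at maintenance, delivery
#: administrations per cycle, and extra acquisition cost (in vials) of the
#: re-initiation/loading schedule after a relapse
DRUGS = {
    "eculizumab": dict(vials_per_cycle=4.0, deliveries_per_cycle=1.0, induction_extra_vials=4.0),
    # 3300 mg every 8 weeks from 1100 mg vials = 3 vials / 4 cycles, one
    # delivery per dose; loading 2400 mg billed pro rata minus the regular
    # maintenance stream already costed in the loading cycle
    "ravulizumab": dict(
        vials_per_cycle=0.75,
        deliveries_per_cycle=0.25,
        induction_extra_vials=2400.0 / 1100.0 - 0.75,
    ),
}


def age_utility_factor(age, male_fraction: float) -> np.ndarray:
    """Population-norm utility at a given age (not yet normalised)."""
    a = np.asarray(age, dtype=float)
    c = _AGE_COEF
    return c["const"] + c["male"] * male_fraction + c["age"] * a + c["age2"] * a**2


@dataclass
class PayoffSchedule:
    """Per-cycle utilities and costs per state plus one-off event costs."""

    utilities: np.ndarray  # (n_cycles, 9)
    costs: np.ndarray  # (n_cycles, 9), GBP per cycle
    transplant_oneoff: float = 0.0  # GBP per incident transplant
    induction_oneoff: float = 0.0  # GBP per incident relapse (re-initiation)
    relapse_transient_disutility: float = 0.0  # utility delta for the relapse cycle
    cost_components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.utilities.shape != self.costs.shape or self.utilities.shape[1] != N_STATES:
            raise ValueError("utilities and costs must both be (n_cycles, 9)")
        if np.any(self.utilities > 1.0 + 1e-12):
            raise ValueError("utilities above 1")


def _base_state_utilities(values: dict[str, float], arm: str, config: ModelConfig) -> np.ndarray:
    """Utility per state at the starting age (before age adjustment)."""
    base = values["utility_baseline_ckd03"]
    u = np.zeros(N_STATES)
    u[IDX["CKD02_OFF"]] = base + values["utility_withdrawal_increment"]
    u[IDX["CKD3_OFF"]] = base + values["utility_withdrawal_increment"]
    u[IDX["CKD02_TX"]] = base
    u[IDX["CKD3_TX"]] = base
    if arm == "withdrawal" and config.relapse_disutility_mode == "persistent":
        u[IDX["CKD02_TX"]] += values["utility_relapse_decrement"]
        u[IDX["CKD3_TX"]] += values["utility_relapse_decrement"]
    u[IDX["CKD4_TX"]] = base + values["disutility_ckd4"]
    u[IDX["ESRD"]] = base + values["disutility_esrd"]
    u[IDX["POST_TX"]] = base + values["disutility_post_transplant"]
    u[IDX["TRANSPLANT"]] = values["utility_transplant_procedure"]
    u[IDX["DEAD"]] = 0.0
    if np.any(np.abs(u) > 1.0):
        raise ValueError("state utility outside [-1, 1]")
    return u


def state_utilities(values: dict[str, float], config: ModelConfig, age: float,
                    arm: str = "withdrawal") -> dict[str, float]:
    """Utility per state at one age (age-adjusted), keyed by state name."""
    u = _base_state_utilities(values, arm, config)
    if config.utility_age_adjustment:
        g = age_utility_factor(age, config.male_fraction) / age_utility_factor(
            config.starting_age, config.male_fraction
        )
        u = u * g
    return dict(zip(STATES, u))


def utility_matrix(values: dict[str, float], config: ModelConfig, arm: str) -> np.ndarray:
    """Per-cycle, per-state utilities over the whole horizon, (n_cycles, 9)."""
    n = config.n_cycles
    u0 = _base_state_utilities(values, arm, config)
    offset = 0.5 if config.half_cycle_correction else 0.0
    ages = config.starting_age + (np.arange(n) + offset) * config.cycle_years
    if config.utility_age_adjustment:
        g = age_utility_factor(ages, config.male_fraction) / age_utility_factor(
            config.starting_age, config.male_fraction
        )
    else:
        g = np.ones(n)
    return np.clip(np.outer(g, u0), -1.0, 1.0)


def _monitoring_schedule(values: dict[str, float], config: ModelConfig) -> np.ndarray:
    """Off-treatment monitoring cost per cycle, phased by time since withdrawal.

    A cycle belongs to a phase if it ends within it (365.25/12-day months):
    with 14-day cycles, month 1 covers the first two cycles, months 2-8 the
    next fifteen, and the long-term rate applies thereafter.
    """
    n = config.n_cycles
    month_days = 365.25 / 12
    months_end = (np.arange(n) + 1) * config.cycle_length_days / month_days
    cost = np.full(n, values["cost_monitoring_withdrawal_month8plus"])
    cost[months_end <= 8 + 1e-9] = values["cost_monitoring_withdrawal_months2_8"]
    cost[months_end <= 1 + 1e-9] = values["cost_monitoring_withdrawal_month1"]
    return cost


def cost_matrix(
    values: dict[str, float],
    config: ModelConfig,
    arm: str,
    drug: str = "eculizumab",
    price_multiplier: float = 1.0,
) -> PayoffSchedule:
    """Per-cycle cost matrix plus one-off costs for one strategy arm."""
    if drug not in DRUGS:
        raise ValueError(f"unknown drug {drug!r}")
    spec = DRUGS[drug]
    n = config.n_cycles
    vial = values[f"cost_{drug}_vial"] * price_multiplier
    drug_cycle = spec["vials_per_cycle"] * vial
    delivery_cycle = (
        (1 - values["pct_home_delivery"])
        * values["cost_hospital_delivery"]
        * spec["deliveries_per_cycle"]
    )
    on_tx_overhead = values["cost_antibiotics"] + values["cost_monitoring_maintenance"]

    comp = {k: np.zeros((n, N_STATES)) for k in
            ("drug", "delivery", "monitoring", "management", "transplant")}
    i = IDX
    on_tx = [i[s] for s in ("CKD02_TX", "CKD3_TX", "CKD4_TX", "ESRD", "TRANSPLANT", "POST_TX")]
    for s in on_tx:
        comp["drug"][:, s] = drug_cycle
        comp["delivery"][:, s] = delivery_cycle
        comp["monitoring"][:, s] = on_tx_overhead

    mon_off = _monitoring_schedule(values, config)
    for s in (i["CKD02_OFF"], i["CKD3_OFF"]):
        comp["monitoring"][:, s] = mon_off
        comp["management"][:, s] = values["cost_management_withdrawal"]

    if arm == "withdrawal" and config.relapse_cost_mode == "persistent":
        for s in (i["CKD02_TX"], i["CKD3_TX"], i["CKD4_TX"]):
            comp["management"][:, s] += values["cost_management_relapse"]
    comp["management"][:, i["CKD4_TX"]] += values["cost_management_ckd4"]
    comp["management"][:, i["ESRD"]] += values["cost_management_esrd"]
    comp["management"][:, i["POST_TX"]] += values["cost_management_post_transplant"]

    costs = sum(comp.values())
    # cost offsets must never drive a state's total below the offsets alone
    floor = values["cost_management_withdrawal"] + values["cost_management_relapse"]
    if costs.min() < min(floor, 0.0) - 1e-9:
        raise ValueError("state cost below the management offsets: mis-assembled schedule")

    induction = spec["induction_extra_vials"] * vial if arm == "withdrawal" else 0.0
    utilities = utility_matrix(values, config, arm)
    transient = (
        values["utility_relapse_decrement"]
        if (arm == "withdrawal" and config.relapse_disutility_mode == "transient")
        else 0.0
    )
    return PayoffSchedule(
        utilities=utilities,
        costs=costs,
        transplant_oneoff=values["cost_transplant"],
        induction_oneoff=induction,
        relapse_transient_disutility=transient,
        cost_components={k: v for k, v in comp.items()},
    )


def state_costs(values: dict[str, float], config: ModelConfig, cycle: int,
                arm: str = "withdrawal", drug: str = "eculizumab") -> dict[str, float]:
    """Cost per state (GBP/cycle) at one cycle, keyed by state name."""
    sched = cost_matrix(values, config, arm, drug)
    return dict(zip(STATES, sched.costs[cycle]))


def relapse_incidence(trace: CohortTrace, matrices: np.ndarray) -> np.ndarray:
    """Incident diagnosed relapses (treatment restarts) during each cycle."""
    occ = trace.occupancy
    i = IDX
    m = matrices
    return (
        occ[:-1, i["CKD02_OFF"]] * (m[:, i["CKD02_OFF"], i["CKD02_TX"]]
                                    + m[:, i["CKD02_OFF"], i["CKD3_TX"]])
        + occ[:-1, i["CKD3_OFF"]] * (m[:, i["CKD3_OFF"], i["CKD3_TX"]]
                                     + m[:, i["CKD3_OFF"], i["CKD4_TX"]])
    )


def transplant_inflow(trace: CohortTrace) -> np.ndarray:
    """Incident transplants during each cycle (the tunnel empties every cycle)."""
    return trace.occupancy[1:, IDX["TRANSPLANT"]]


@dataclass
class ArmOutcomes:
    """Discounted totals for one strategy arm."""

    arm: str
    life_years: float
    qalys: float
    cost: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)


@dataclass
class EconomicOutcomes:
    """Incremental comparison of withdrawal versus lifelong maintenance."""

    withdrawal: ArmOutcomes
    maintenance: ArmOutcomes
    wtp_grid: tuple[float, ...] = ()

    @property
    def delta_qalys(self) -> float:
        return self.withdrawal.qalys - self.maintenance.qalys

    @property
    def delta_cost(self) -> float:
        return self.withdrawal.cost - self.maintenance.cost

    @property
    def delta_life_years(self) -> float:
        return self.withdrawal.life_years - self.maintenance.life_years

    @property
    def label(self) -> str:
        dq, dc = self.delta_qalys, self.delta_cost
        if dq == 0 and dc == 0:
            return "equivalent"
        if dq > 0 and dc < 0:
            return "dominant"
        if dq < 0 and dc > 0:
            return "dominated"
        return "icer"

    @property
    def icer(self) -> float | None:
        """Cost per QALY, reported only off the dominance quadrants."""
        if self.label != "icer" or self.delta_qalys == 0:
            return None
        return self.delta_cost / self.delta_qalys

    def nmb(self, wtp: float) -> float:
        """Incremental net monetary benefit lambda * dQ - dC."""
        return wtp * self.delta_qalys - self.delta_cost

    def nmb_curve(self) -> np.ndarray:
        return np.array([self.nmb(w) for w in self.wtp_grid])

    def summary_row(self) -> dict:
        lab = self.label
        return {
            "ly_maintenance": self.maintenance.life_years,
            "ly_withdrawal": self.withdrawal.life_years,
            "qaly_maintenance": self.maintenance.qalys,
            "qaly_withdrawal": self.withdrawal.qalys,
            "cost_maintenance": self.maintenance.cost,
            "cost_withdrawal": self.withdrawal.cost,
            "delta_qalys": self.delta_qalys,
            "delta_cost": self.delta_cost,
            "icer": "Withdrawal dominant" if lab == "dominant" else (self.icer or lab),
        }


def accumulate(
    trace: CohortTrace,
    payoffs: PayoffSchedule,
    config: ModelConfig,
    matrices: np.ndarray | None = None,
) -> tuple[float, float]:
    """Discounted (QALYs, cost) for one arm.

    Per-cycle payoffs are applied to the half-cycle-corrected occupancy and
    discounted at the cycle midpoint; one-off costs (transplant surgery,
    treatment re-initiation) and the transient relapse disutility attach to
    incident transitions within each cycle.
    """
    occ = cycle_occupancy(trace, config)
    n = occ.shape[0]
    if payoffs.utilities.shape[0] != n:
        raise ValueError("payoff horizon does not match the trace")
    disc = discount_factors(config, n)
    dy = config.cycle_years
    qaly = float(np.einsum("ts,ts,t->", occ, payoffs.utilities, disc) * dy)
    cost = float(np.einsum("ts,ts,t->", occ, payoffs.costs, disc))
    if payoffs.transplant_oneoff:
        cost += float(np.sum(transplant_inflow(trace) * disc) * payoffs.transplant_oneoff)
    if matrices is not None and (payoffs.induction_oneoff or payoffs.relapse_transient_disutility):
        inc = relapse_incidence(trace, matrices)
        cost += float(np.sum(inc * disc) * payoffs.induction_oneoff)
        qaly += float(np.sum(inc * disc) * payoffs.relapse_transient_disutility * dy)
    return qaly, cost


def incremental(
    withdrawal: ArmOutcomes, maintenance: ArmOutcomes, wtp_grid=None
) -> EconomicOutcomes:
    """Incremental cost-effectiveness of withdrawal versus maintenance."""
    grid = tuple(wtp_grid) if wtp_grid is not None else ()
    return EconomicOutcomes(withdrawal=withdrawal, maintenance=maintenance, wtp_grid=grid)
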