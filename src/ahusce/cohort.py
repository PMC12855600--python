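"""Discrete-time Markov cohort engine for the two treatment strategies.

Nine health states track CKD severity and treatment status:

====================  =====================================================
``CKD02_OFF``         CKD stages 0-2, off treatment (monitoring)
``CKD02_TX``          CKD 0-2 on eculizumab (maintenance, or post-relapse)
``CKD3_OFF``          CKD 3, off treatment
``CKD3_TX``           CKD 3 on eculizumab
``CKD4_TX``           CKD 4, on treatment, may progress to kidney failure
``ESRD``              end-stage renal disease (dialysis), excess mortality
``TRANSPLANT``        kidney transplant procedure — single-cycle tunnel
``POST_TX``           post-transplant care, excess mortality
``DEAD``              absorbing
====================  =====================================================

Cycles are two weeks; background mortality is an age/sex life-table lookup
applied competitively (clinical transitions scaled by one minus the death
probability), and patients on treatment at CKD 0-2/3 never progress.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelConfig, ParameterSet

STATES = (
    "CKD02_OFF",
    "CKD02_TX",
    "CKD3_OFF",
    "CKD3_TX",
    "CKD4_TX",
    "ESRD",
    "TRANSPLANT",
    "POST_TX",
    "DEAD",
)
IDX = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

#: states whose occupants receive a C5 inhibitor (drug + delivery costs)
ON_TREATMENT = ("CKD02_TX", "CKD3_TX", "CKD4_TX", "ESRD", "TRANSPLANT", "POST_TX")
#: states carrying the per-cycle excess mortality of advanced disease
EXCESS_MORTALITY = ("ESRD", "TRANSPLANT", "POST_TX")
#: off-treatment monitored states
MONITORED_OFF = ("CKD02_OFF", "CKD3_OFF")

ARMS = ("maintenance", "withdrawal")


@dataclass
class LifeTable:
    """Annual death probabilities by single year of age and sex."""

    ages: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.q_male = np.asarray(self.q_male, dtype=float)
        self.q_female = np.asarray(self.q_female, dtype=float)
        for q in (self.q_male, self.q_female):
            if np.any((q < 0) | (q > 1)):
                raise ValueError("life-table probabilities must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["age"].to_numpy(), df["q_male"].to_numpy(), df["q_female"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"age": self.ages, "q_male": self.q_male, "q_female": self.q_female}
        ).to_csv(path, index=False)

    def annual_q(self, age: float, male_fraction: float) -> float:
        """Sex-mixed annual death probability at the integer age attained."""
        a = int(np.floor(age))
        if a < self.ages[0] or a > self.ages[-1]:
            raise ValueError(f"age {age} outside life table range "
                             f"[{self.ages[0]}, {self.ages[-1]}]")
        i = np.searchsorted(self.ages, a)
        return male_fraction * self.q_male[i] + (1 - male_fraction) * self.q_female[i]


def load_reference_life_table() -> LifeTable:
    """The bundled synthetic life table (see its file header)."""
    res = resources.files("ahusce.data").joinpath("life_table_synthetic.csv")
    with resources.as_file(res) as p:
        return LifeTable.from_csv(p)


def background_mortality(
    age: float, male_fraction: float, table: LifeTable, cycles_per_year: float
) -> float:
    """Per-cycle background death probability at a given age.

    The sex-mixed annual probability q is converted with
    1 - (1 - q)^(1/cycles_per_year).
    """
    q = table.annual_q(age, male_fraction)
    return 1.0 - (1.0 - q) ** (1.0 / cycles_per_year)


def cycle_death_probabilities(
    config: ModelConfig, table: LifeTable, n_cycles: int | None = None
) -> np.ndarray:
    """Background per-cycle death probability for every model cycle."""
    n = config.n_cycles if n_cycles is None else n_cycles
    ages = config.starting_age + np.arange(n) * config.cycle_years
    ai = np.floor(ages).astype(int)
    if ai[-1] > table.ages[-1]:
        raise ValueError("life table does not cover the model horizon")
    lookup = config.male_fraction * table.q_male + (1 - config.male_fraction) * table.q_female
    q_annual = lookup[np.searchsorted(table.ages, ai)]
    return 1.0 - (1.0 - q_annual) ** (1.0 / config.cycles_per_year)


def build_transition_matrices(
    arm: str,
    values: dict[str, float],
    relapse_probs: np.ndarray,
    table: LifeTable,
    config: ModelConfig,
) -> np.ndarray:
    """All per-cycle transition matrices, shape (n_cycles, 9, 9).

    Death is applied first; the remaining probability mass is split by the
    clinical transitions.  A diagnosed relapse restarts treatment, with a
    chance (the relapse-progression split) of presenting one CKD stage
    further on.  In the maintenance arm the cohort stays in its on-treatment
    CKD state until death.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    n = config.n_cycles
    p_die = cycle_death_probabilities(config, table, n)
    if arm == "withdrawal":
        if len(relapse_probs) < n:
            raise ValueError("relapse_probs shorter than the model horizon")
        p_rel = np.asarray(relapse_probs[:n], dtype=float)
    else:
        p_rel = np.zeros(n)

    prog02 = values["relapse_progression_ckd02"]
    prog3 = values["relapse_progression_ckd3"]
    p45 = values["ckd4_to_esrd"]
    p5t = values["esrd_to_transplant"]
    if config.advanced_progression_annual:
        # annual probabilities converted to the 2-week cycle
        p45 = 1.0 - (1.0 - p45) ** (1.0 / config.cycles_per_year)
        p5t = 1.0 - (1.0 - p5t) ** (1.0 / config.cycles_per_year)
    pfail = values["transplant_failure"]
    exc = {
        "ESRD": values["excess_mortality_esrd"],
        "TRANSPLANT": values["excess_mortality_transplant"],
        "POST_TX": values["excess_mortality_post_transplant"],
    }

    M = np.zeros((n, N_STATES, N_STATES))
    i = IDX

    def death(extra: float = 0.0) -> np.ndarray:
        return np.clip(p_die + extra, 0.0, 1.0)

    # CKD02_OFF: relapse -> 75% restart at CKD 0-2, 25% restart at CKD 3
    d = death()
    alive = 1 - d
    M[:, i["CKD02_OFF"], i["DEAD"]] = d
    M[:, i["CKD02_OFF"], i["CKD02_TX"]] = alive * p_rel * (1 - prog02)
    M[:, i["CKD02_OFF"], i["CKD3_TX"]] = alive * p_rel * prog02
    M[:, i["CKD02_OFF"], i["CKD02_OFF"]] = alive * (1 - p_rel)

    # CKD3_OFF: relapse -> 75% restart at CKD 3, 25% restart at CKD 4
    M[:, i["CKD3_OFF"], i["DEAD"]] = d
    M[:, i["CKD3_OFF"], i["CKD3_TX"]] = alive * p_rel * (1 - prog3)
    M[:, i["CKD3_OFF"], i["CKD4_TX"]] = alive * p_rel * prog3
    M[:, i["CKD3_OFF"], i["CKD3_OFF"]] = alive * (1 - p_rel)

    # on-treatment CKD 0-2 / CKD 3: no progression
    for s in ("CKD02_TX", "CKD3_TX"):
        M[:, i[s], i["DEAD"]] = d
        M[:, i[s], i[s]] = alive

    # CKD4 on treatment: may progress to kidney failure
    M[:, i["CKD4_TX"], i["DEAD"]] = d
    M[:, i["CKD4_TX"], i["ESRD"]] = alive * p45
    M[:, i["CKD4_TX"], i["CKD4_TX"]] = alive * (1 - p45)

    # ESRD: may receive a transplant; excess mortality
    de = death(exc["ESRD"])
    M[:, i["ESRD"], i["DEAD"]] = de
    M[:, i["ESRD"], i["TRANSPLANT"]] = (1 - de) * p5t
    M[:, i["ESRD"], i["ESRD"]] = (1 - de) * (1 - p5t)

    # transplant tunnel: exits after one cycle; graft failure returns to ESRD
    dt = death(exc["TRANSPLANT"])
    M[:, i["TRANSPLANT"], i["DEAD"]] = dt
    M[:, i["TRANSPLANT"], i["ESRD"]] = (1 - dt) * pfail
    M[:, i["TRANSPLANT"], i["POST_TX"]] = (1 - dt) * (1 - pfail)

    # post-transplant: excess mortality; graft failure optional per cycle
    dp = death(exc["POST_TX"])
    M[:, i["POST_TX"], i["DEAD"]] = dp
    if config.transplant_failure_mode == "per_cycle":
        M[:, i["POST_TX"], i["ESRD"]] = (1 - dp) * pfail
        M[:, i["POST_TX"], i["POST_TX"]] = (1 - dp) * (1 - pfail)
    else:
        M[:, i["POST_TX"], i["POST_TX"]] = 1 - dp

    M[:, i["DEAD"], i["DEAD"]] = 1.0

    rows = M.sum(axis=2)
    if not np.allclose(rows, 1.0, atol=1e-9):
        raise RuntimeError("internal error: transition rows do not sum to 1")
    return M


def transition_matrix(
    cycle: int,
    arm: str,
    params: ParameterSet,
    relapse_probs: np.ndarray,
    table: LifeTable,
) -> np.ndarray:
    """Single-cycle row-stochastic transition matrix (convenience wrapper)."""
    M = build_transition_matrices(arm, params.point_values(), relapse_probs, table, params.config)
    return M[cycle]


@dataclass
class CohortTrace:
    """Per-cycle state occupancy for one strategy arm."""

    occupancy: np.ndarray  # (n_cycles + 1, 9)
    times: np.ndarray  # years from model start at each cycle boundary
    arm: str

    def __post_init__(self) -> None:
        occ = self.occupancy
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("trace rows must sum to 1")
        if occ.min() < -1e-12:
            raise ValueError("negative occupancy")
        dead = occ[:, IDX["DEAD"]]
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("DEAD occupancy must be non-decreasing")

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, IDX["DEAD"]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "time_years", self.times)
        df.insert(0, "cycle", np.arange(len(self.times)))
        return df


def initial_distribution(arm: str, values: dict[str, float]) -> np.ndarray:
    """Baseline disease split: CKD 0-2 share with CKD 3 as the complement."""
    p02 = values["pct_ckd02"]
    init = np.zeros(N_STATES)
    if arm == "withdrawal":
        init[IDX["CKD02_OFF"]] = p02
        init[IDX["CKD3_OFF"]] = 1 - p02
    else:
        init[IDX["CKD02_TX"]] = p02
        init[IDX["CKD3_TX"]] = 1 - p02
    return init


def run_cohort(
    initial: np.ndarray | None,
    arm: str,
    values: dict[str, float],
    relapse_probs: np.ndarray,
    table: LifeTable,
    config: ModelConfig,
    matrices: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate the cohort through every cycle: row i+1 = row i @ M(i)."""
    if matrices is None:
        matrices = build_transition_matrices(arm, values, relapse_probs, table, config)
    if initial is None:
        initial = initial_distribution(arm, values)
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,) or abs(initial.sum() - 1) > 1e-9 or initial.min() < 0:
        raise ValueError("initial distribution must be a length-9 probability vector")
    n = matrices.shape[0]
    occ = np.empty((n + 1, N_STATES))
    occ[0] = initial
    for t in range(n):
        occ[t + 1] = occ[t] @ matrices[t]
    times = np.arange(n + 1) * config.cycle_years
    return CohortTrace(occupancy=occ, times=times, arm=arm)


def discount_factors(config: ModelConfig, n: int | None = None) -> np.ndarray:
    """Per-cycle discount factors.

    With the half-cycle correction the cycle payoff is valued at the cycle
    midpoint; otherwise at the cycle start.
    """
    n = config.n_cycles if n is None else n
    t = np.arange(n) * config.cycle_years
    if config.half_cycle_correction:
        t = t + config.cycle_years / 2
    return (1.0 + config.discount_rate) ** (-t)


def cycle_occupancy(trace: CohortTrace, config: ModelConfig) -> np.ndarray:
    """Occupancy attributed to each cycle, shape (n_cycles, 9).

    Trapezoid of the two cycle-boundary rows under the half-cycle
    correction, else the start-of-cycle row.
    """
    occ = trace.occupancy
    if config.half_cycle_correction:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def discounted_life_years(trace: CohortTrace, config: ModelConfig) -> float:
    """Discounted life years implied by a cohort trace."""
    occ = cycle_occupancy(trace, config)
    alive = 1.0 - occ[:, IDX["DEAD"]]
    return float(np.sum(alive * discount_factors(config, len(alive))) * config.cycle_years)
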