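"""Synthetic-data generators for every input the pipeline consumes.

No patient-level data were ever deposited for this trial, so the package
generates statistically faithful stand-ins: right-censored relapse times
(lognormal with the published 4/28 two-year event fraction), visit-level
trial panels (random-intercept utility and cost models with heavy
instrument missingness and one extreme outlier patient) and a
Gompertz-Makeham life table calibrated to UK-like life expectancy.  All
outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LifeTable
from .survival import SurvivalData
from .trial import EQ5D_COLUMNS, SCHEDULED_MONTHS, TrialPanel

__all__ = [
    "GeneratorConfig",
    "generate_relapse_times",
    "generate_trial_panel",
    "generate_life_table",
    "MAKEHAM_DEFAULT",
]

#: Gompertz-Makeham hazard m(a) = A + B e^(C a); sex multipliers on the
#: hazard; calibrated so the 51% male mixed life expectancy at birth is 81.
MAKEHAM_DEFAULT = (2.0e-4, 1.156550048874255e-05, 0.105)
SEX_HAZARD_MULTIPLIERS = (1.30, 0.78)  # male, female


def _relapse_mu(sigma: float, censor_months: float, event_fraction: float) -> float:
    """Location of the lognormal with P(T < censor) = event_fraction."""
    return float(np.log(censor_months) - sigma * stats.norm.ppf(event_fraction))


@dataclass
class GeneratorConfig:
    """Study conditions of the emulated trial (defaults = published design)."""

    n_withdrawal: int = 28
    n_comparison: int = 11
    seed: int = 0

    # time-to-relapse model (months); mu is solved from the event fraction
    relapse_sigma: float = 1.5
    relapse_event_fraction: float = 4 / 28
    censor_months: float = 24.0
    relapse_mu_override: float | None = None  # bypass the solved location

    # visit-level utility model
    utility_baseline_mean: float = 0.86
    utility_baseline_sd: float = 0.04
    utility_intercept_sd: float = 0.02
    utility_residual_sd: float = 0.03
    utility_baseline_slope: float = 0.959
    utility_month_slope: float = 0.002
    utility_age_effect: float = 0.001
    utility_male_effect: float = -0.016
    utility_withdrawal_effect: float = 0.006
    utility_relapse_effect: float = -0.015
    utility_const: float = 0.028

    # monthly healthcare-cost model (GBP)
    cost_baseline_mean: float = 400.0
    cost_baseline_sd: float = 200.0
    cost_intercept_sd: float = 100.0
    cost_residual_sd: float = 200.0
    cost_baseline_slope: float = 0.38
    cost_month_slope: float = 10.0
    cost_age_effect: float = -3.0
    cost_male_effect: float = 241.0
    cost_withdrawal_effect: float = -70.0
    cost_relapse_effect: float = -325.0
    cost_const: float = 800.0

    # per-patient probability of at least one missing instrument
    p_any_missing_eq5d: tuple[float, float] = (0.61, 0.91)  # withdrawal, comparison
    p_any_missing_cost: tuple[float, float] = (0.57, 0.91)

    # outlier injection
    n_outliers: int = 1
    outlier_utility_shift: float = -0.35
    outlier_cost_multiplier: float = 15.0

    # demographics
    age_mean: float = 45.0
    age_sd: float = 12.0
    male_fraction: float = 0.51

    def __post_init__(self) -> None:
        if self.n_withdrawal < 1 or self.n_comparison < 1:
            raise ValueError("cohort sizes must be >= 1")
        for p in (*self.p_any_missing_eq5d, *self.p_any_missing_cost):
            if not 0 <= p < 1:
                raise ValueError("missingness probabilities must lie in [0, 1)")

    @property
    def relapse_mu(self) -> float:
        if self.relapse_mu_override is not None:
            return self.relapse_mu_override
        return _relapse_mu(self.relapse_sigma, self.censor_months, self.relapse_event_fraction)

    def per_visit_missing_rate(self, instrument: str, arm: str) -> float:
        """MCAR per-visit rate implied by the per-patient any-missing target."""
        target = dict(eq5d=self.p_any_missing_eq5d, cost=self.p_any_missing_cost)[instrument]
        p_any = target[0 if arm == "withdrawal" else 1]
        return 1.0 - (1.0 - p_any) ** (1.0 / len(SCHEDULED_MONTHS))


def generate_relapse_times(config: GeneratorConfig | None = None,
                           n: int | None = None,
                           seed: int | None = None) -> SurvivalData:
    """Right-censored relapse times for a withdrawal cohort."""
    config = config or GeneratorConfig()
    n = n if n is not None else config.n_withdrawal
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = rng.lognormal(config.relapse_mu, config.relapse_sigma, n)
    events = (t < config.censor_months).astype(int)
    return SurvivalData(np.minimum(t, config.censor_months), events)


def _severity_profile(utility: float) -> tuple[int, ...]:
    """Render a utility as a plausible five-dimension response profile.

    A quantised representation used for format round-trips; the panel's
    ``utility`` column (the model value) is what analyses consume.
    """
    if np.isnan(utility):
        return (np.nan,) * 5  # type: ignore[return-value]
    sev = float(np.clip((1.0 - utility) / 1.2, 0.0, 1.0))
    level = 1 + int(round(4 * sev))
    return tuple(int(np.clip(level + d, 1, 5)) for d in (0, 0, -1, 0, 1))


def generate_trial_panel(config: GeneratorConfig | None = None) -> TrialPanel:
    """Visit-level panel for both cohorts with missingness and one outlier.

    Utilities follow a random-intercept linear model (truncated at 1);
    monthly costs a right-skewed random-intercept model (floored at 0).
    The last withdrawal patients (``n_outliers`` of them) get an extreme
    utility shift and cost multiplier, mirroring the outlier the trial
    flagged.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    months = np.array(SCHEDULED_MONTHS, dtype=float)
    rows = []
    patients = [("withdrawal", f"W{i + 1:02d}") for i in range(config.n_withdrawal)]
    patients += [("comparison", f"C{i + 1:02d}") for i in range(config.n_comparison)]
    outlier_ids = {f"W{config.n_withdrawal - i:02d}" for i in range(config.n_outliers)}

    for arm, pid in patients:
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 80))
        male = int(rng.random() < config.male_fraction)
        wd = 1.0 if arm == "withdrawal" else 0.0
        b_u = float(np.clip(
            rng.normal(config.utility_baseline_mean, config.utility_baseline_sd), 0.2, 1.0
        ))
        b_c = float(max(rng.normal(config.cost_baseline_mean, config.cost_baseline_sd), 0.0))
        u_i = rng.normal(0.0, config.utility_intercept_sd)
        c_i = rng.normal(0.0, config.cost_intercept_sd)
        relapse_time = (
            rng.lognormal(config.relapse_mu, config.relapse_sigma) if wd else np.inf
        )
        is_outlier = pid in outlier_ids

        miss_u = rng.random(len(months)) < config.per_visit_missing_rate("eq5d", arm)
        miss_c = rng.random(len(months)) < config.per_visit_missing_rate("cost", arm)

        for j, m in enumerate(months):
            rel = float(wd and m >= relapse_time)
            if m == 0:
                util = b_u
                cost = b_c
            else:
                util = (
                    config.utility_const
                    + config.utility_baseline_slope * b_u
                    + config.utility_month_slope * m
                    + config.utility_age_effect * age
                    + config.utility_male_effect * male
                    + config.utility_withdrawal_effect * wd
                    + config.utility_relapse_effect * rel
                    + u_i
                    + rng.normal(0.0, config.utility_residual_sd)
                )
                cost = (
                    config.cost_const
                    + config.cost_baseline_slope * b_c
                    + config.cost_month_slope * m
                    + config.cost_age_effect * age
                    + config.cost_male_effect * male
                    + config.cost_withdrawal_effect * wd
                    + config.cost_relapse_effect * rel
                    + c_i
                    + rng.normal(0.0, config.cost_residual_sd)
                )
            if is_outlier:
                util += config.outlier_utility_shift
                cost *= config.outlier_cost_multiplier
            util = float(min(util, 1.0))
            cost = float(max(cost, 0.0))
            u_obs = np.nan if miss_u[j] else util
            c_obs = np.nan if miss_c[j] else cost
            profile = _severity_profile(u_obs)
            rows.append({
                "patient_id": pid, "arm": arm, "age": age, "male": male,
                "month": int(m),
                **dict(zip(EQ5D_COLUMNS, profile)),
                "utility": u_obs, "monthly_cost": c_obs, "relapse": int(rel),
            })
    return TrialPanel(pd.DataFrame(rows))


def generate_life_table(
    makeham: tuple[float, float, float] = MAKEHAM_DEFAULT,
    max_age: int = 100,
) -> LifeTable:
    """Synthetic annual life table from a Gompertz-Makeham hazard.

    Hazards exceeding probability 1 are clipped (with a warning) — only
    relevant for extreme parameter choices.
    """
    A, B, C = makeham
    if A < 0 or B <= 0 or C <= 0:
        raise ValueError("require A >= 0, B > 0, C > 0")
    ages = np.arange(0, max_age + 1)
    m = A + B * np.exp(C * ages)
    mm, mf = SEX_HAZARD_MULTIPLIERS
    q_male = 1.0 - np.exp(-m * mm)
    q_female = 1.0 - np.exp(-m * mf)
    if np.any(q_male > 1) or np.any(q_female > 1):
        import warnings

        warnings.warn("life-table probabilities clipped at 1")
    return LifeTable(ages, np.clip(q_male, 0, 1), np.clip(q_female, 0, 1))


def life_expectancy(table: LifeTable, male_fraction: float = 0.51) -> float:
    """Period life expectancy at birth from the table (trapezoidal l(x))."""
    # sex-specific cohorts mixed at birth
    def e0(qs):
        lx = np.concatenate([[1.0], np.cumprod(1 - qs)])
        return float((lx[:-1] + lx[1:]).sum() / 2)

    return male_fraction * e0(table.q_male) + (1 - male_fraction) * e0(table.q_female)
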