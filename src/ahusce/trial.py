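"""Patient-level trial-panel analysis.

Visit-level EQ-5D responses are mapped to utilities through a pluggable
crosswalk table, per-patient QALYs are accumulated as the trapezoidal area
under utility versus time, missingness is reported per arm and instrument
(never imputed), and utility/cost changes associated with treatment
withdrawal and relapse are estimated with random-intercept panel
regressions on all observed visits (available-case analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TrialPanel",
    "PanelModelResult",
    "SCHEDULED_MONTHS",
    "synthetic_crosswalk",
    "map_eq5d",
    "auc_qalys",
    "missingness_report",
    "fit_panel_model",
]

SCHEDULED_MONTHS = (0, 1, 3, 6, 9, 12, 18, 24)
EQ5D_COLUMNS = tuple(f"eq5d_{i}" for i in range(1, 6))
PANEL_COLUMNS = (
    "patient_id", "arm", "age", "male", "month",
    *EQ5D_COLUMNS, "utility", "monthly_cost", "relapse",
)


@dataclass
class TrialPanel:
    """Visit-level records for the withdrawal and comparison cohorts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        bad = set(self.data["arm"].unique()) - {"withdrawal", "comparison"}
        if bad:
            raise ValueError(f"unknown arm labels: {bad}")
        off = set(self.data["month"].unique()) - set(SCHEDULED_MONTHS)
        if off:
            raise ValueError(f"off-schedule visit months: {sorted(off)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialPanel":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def exclude_patients(self, ids) -> "TrialPanel":
        """Drop listed patients (outlier control); never silent — returns new panel."""
        ids = set(np.atleast_1d(ids).tolist())
        unknown = ids - set(self.data["patient_id"])
        if unknown:
            raise ValueError(f"unknown patient ids: {sorted(unknown)}")
        return TrialPanel(self.data[~self.data["patient_id"].isin(ids)].copy())


def synthetic_crosswalk() -> pd.DataFrame:
    """A SYNTHETIC EQ-5D-5L value set for testing (not the published tariff).

    Monotone in severity on every dimension, full health (11111) = 1.0 and
    worst health (55555) = -0.2; generated programmatically so no data file
    ships with the package.
    """
    weights = np.array([0.28, 0.25, 0.24, 0.23, 0.20])  # sum 1.2
    levels = np.stack(np.meshgrid(*[np.arange(1, 6)] * 5, indexing="ij"), -1).reshape(-1, 5)
    dec = (weights[None, :] * ((levels - 1) / 4.0) ** 1.3).sum(axis=1)
    profiles = ["".join(map(str, row)) for row in levels]
    return pd.DataFrame({"profile": profiles, "utility": 1.0 - dec})


def map_eq5d(responses, crosswalk: pd.DataFrame) -> float:
    """Utility for one five-dimension response profile.

    Any missing dimension propagates as a missing utility (no imputation).
    """
    arr = np.asarray(list(responses), dtype=float)
    if arr.shape != (5,):
        raise ValueError("a profile has exactly five dimensions")
    if np.any(np.isnan(arr)):
        return float("nan")
    profile = "".join(str(int(x)) for x in arr)
    lookup = crosswalk.set_index("profile")["utility"] \
        if crosswalk.index.name != "profile" else crosswalk["utility"]
    if profile not in lookup.index:
        raise KeyError(f"profile {profile} absent from the crosswalk")
    return float(lookup.loc[profile])


def auc_qalys(utilities, months) -> float:
    """Trapezoidal QALYs over follow-up for one patient.

    Complete-case rule: at least two observed visits including baseline;
    otherwise the patient is incomplete and NaN is returned.
    """
    u = np.asarray(utilities, dtype=float)
    m = np.asarray(months, dtype=float)
    keep = ~np.isnan(u)
    u, m = u[keep], m[keep]
    if len(u) < 2 or m.min() > 0:
        return float("nan")
    order = np.argsort(m)
    return float(np.trapezoid(u[order], m[order] / 12.0))


def missingness_report(panel: TrialPanel) -> pd.DataFrame:
    """Per-arm, per-instrument completeness counts.

    A patient is a complete record when every scheduled visit has the
    instrument observed.
    """
    rows = []
    for instrument, col in (("eq5d", "utility"), ("cost", "monthly_cost")):
        for arm, grp in panel.data.groupby("arm"):
            per_patient = grp.groupby("patient_id")[col].apply(
                lambda s: s.notna().sum()
            )
            n = len(per_patient)
            complete = int((per_patient == len(SCHEDULED_MONTHS)).sum())
            rows.append({
                "instrument": instrument,
                "arm": arm,
                "n_patients": n,
                "complete_records": complete,
                "prop_any_missing": 1.0 - complete / n,
            })
    return pd.DataFrame(rows)


@dataclass
class PanelModelResult:
    """Random-intercept regression estimates in published-table layout."""

    outcome: str
    table: pd.DataFrame  # index: covariate; columns: coef, se, p, ci_low, ci_high
    n_obs: int
    n_patients: int

    def coef(self, name: str) -> float:
        return float(self.table.loc[name, "coef"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


_COVARIATES = ("month", "age", "male", "baseline", "withdrawal", "relapse", "const")


def fit_panel_model(panel: TrialPanel, outcome: str = "utility") -> PanelModelResult:
    """Random-intercept linear model of visit-level utility or monthly cost.

    Post-baseline visits with an observed outcome enter the estimation
    (available case); covariates are visit month, age, sex, the patient's
    baseline outcome, a withdrawal-arm indicator and a post-relapse
    indicator.  Estimated by REML via a patient-level random intercept.
    """
    if outcome not in ("utility", "monthly_cost"):
        raise ValueError("outcome must be 'utility' or 'monthly_cost'")
    df = panel.data
    baseline = (
        df[df["month"] == 0].set_index("patient_id")[outcome].rename("baseline")
    )
    work = df[df["month"] > 0].join(baseline, on="patient_id")
    work = work.dropna(subset=[outcome, "baseline"]).copy()
    n_per = work.groupby("patient_id").size()
    if (n_per >= 2).sum() < 2:
        raise ValueError("need at least two patients with two post-baseline visits")
    work["withdrawal"] = (work["arm"] == "withdrawal").astype(float)
    work["male"] = work["male"].astype(float)
    work["relapse"] = work["relapse"].astype(float)
    X = work[["month", "age", "male", "baseline", "withdrawal", "relapse"]].astype(float)
    X = sm.add_constant(X, prepend=False, has_constant="add")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = [c for c in X.columns if X[c].nunique() <= 1 and c != "const"]
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = [f"{a}~{b}" for a in corr.index for b in corr.columns
                 if a < b and corr.loc[a, b] > 0.999]
        raise ValueError(f"singular design: degenerate columns {bad or pairs}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(work[outcome].astype(float), X, groups=work["patient_id"])
        fit = None
        for method in ("bfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if fit is None:
            raise RuntimeError("random-intercept fit failed with every optimiser")

    params = fit.params[list(X.columns)]
    bse = fit.bse[list(X.columns)]
    conf = fit.conf_int().loc[list(X.columns)]
    table = pd.DataFrame({
        "coef": params,
        "se": bse,
        "p": fit.pvalues[list(X.columns)],
        "ci_low": conf[0],
        "ci_high": conf[1],
    })
    table.index.name = "covariate"
    return PanelModelResult(
        outcome=outcome,
        table=table,
        n_obs=int(len(work)),
        n_patients=int(work["patient_id"].nunique()),
    )
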