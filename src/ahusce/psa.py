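"""Probabilistic and deterministic (one-way) sensitivity analysis.

The PSA redraws every uncertain parameter from its moment-matched family
and the fitted relapse-curve parameters from their asymptotic normal (on
the estimation scale), reruns both strategy arms, and summarises the joint
distribution of incremental costs and QALYs: means, 95% credible intervals
(equal-tailed percentiles), cost-effectiveness-plane quadrant shares and
the cost-effectiveness acceptability curve (CEAC).

The tornado analysis perturbs one parameter at a time to mean +/- 1.96 SE
(clipped to its domain) and ranks parameters by the width of the induced
swing in incremental net monetary benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survival
from .cohort import LifeTable
from .params import ParameterSet
from .pipeline import base_case_inputs, run_arm

logger = logging.getLogger(__name__)

__all__ = ["PSAResults", "run_psa", "ceac", "quadrant_probability", "tornado"]

QUADRANTS = ("dominant", "more_effective_more_costly",
             "less_effective_less_costly", "dominated")


@dataclass
class PSAResults:
    """Per-iteration incremental outcomes plus run metadata."""

    draws: pd.DataFrame  # columns: dq, dc, dly, qaly_w, qaly_m, cost_w, cost_m
    seed: int
    n_iterations: int
    n_redrawn: int = 0
    wtp_grid: tuple[float, ...] = ()

    def mean(self, col: str) -> float:
        return float(self.draws[col].mean())

    def credible_interval(self, col: str, level: float = 0.95) -> tuple[float, float]:
        lo, hi = np.quantile(self.draws[col], [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def summary(self) -> dict:
        out = {"n_iterations": self.n_iterations, "seed": self.seed,
               "n_redrawn": self.n_redrawn}
        for col in ("dq", "dc", "dly"):
            lo, hi = self.credible_interval(col)
            out[col] = {"mean": self.mean(col), "cri_low": lo, "cri_high": hi}
        out["quadrants"] = quadrant_probability(self)
        return out


def _valid_draw(values: dict[str, float]) -> bool:
    """Reject joint draws that violate payoff domains (then redraw)."""
    base = values["utility_baseline_ckd03"]
    if not 0 < base + values["utility_withdrawal_increment"] <= 1:
        return False
    if not 0 < base + values["utility_relapse_decrement"] <= 1:
        return False
    for k in ("disutility_ckd4", "disutility_esrd", "disutility_post_transplant"):
        if not -1 <= base + values[k] <= 1:
            return False
    for k in ("excess_mortality_esrd", "excess_mortality_transplant",
              "excess_mortality_post_transplant"):
        if values[k] < 0:
            return False
    return True


def run_psa(
    params: ParameterSet,
    relapse_fit: survival.SurvivalFit | None = None,
    n: int = 5000,
    seed: int = 0,
    table: LifeTable | None = None,
    drug: str = "eculizumab",
) -> PSAResults:
    """Monte-Carlo propagation of parameter uncertainty through both arms."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params, table, relapse_fit = base_case_inputs(params, table, relapse_fit)
    config = params.config
    rng = np.random.default_rng(seed)
    rows = np.empty((n, 7))
    n_redrawn = 0
    for it in range(n):
        for _attempt in range(100):
            values = params.sample(rng)
            if _valid_draw(values):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a valid parameter set in 100 tries")
        fit_draw = survival.sample_fit_uncertainty(relapse_fit, rng)
        relapse_probs = survival.cycle_probabilities(fit_draw, config)
        w = run_arm("withdrawal", values, config, table, relapse_probs, drug=drug)
        m = run_arm("maintenance", values, config, table, relapse_probs, drug=drug)
        rows[it] = (w.qalys - m.qalys, w.cost - m.cost,
                    w.life_years - m.life_years,
                    w.qalys, m.qalys, w.cost, m.cost)
    if n_redrawn:
        logger.info("PSA redrew %d invalid parameter sets", n_redrawn)
    draws = pd.DataFrame(
        rows, columns=["dq", "dc", "dly", "qaly_w", "qaly_m", "cost_w", "cost_m"]
    )
    return PSAResults(draws=draws, seed=seed, n_iterations=n,
                      n_redrawn=n_redrawn, wtp_grid=tuple(config.wtp_grid))


def ceac(results: PSAResults, wtp_grid=None) -> pd.DataFrame:
    """Probability that withdrawal is cost-effective at each willingness-to-pay."""
    grid = np.asarray(wtp_grid if wtp_grid is not None else results.wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    dq = results.draws["dq"].to_numpy()
    dc = results.draws["dc"].to_numpy()
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    return pd.DataFrame({"wtp": grid, "probability": (nmb > 0).mean(axis=1)})


def quadrant_probability(results: PSAResults) -> dict[str, float]:
    """Share of iterations in each cost-effectiveness-plane quadrant."""
    dq = results.draws["dq"].to_numpy()
    dc = results.draws["dc"].to_numpy()
    n = len(dq)
    out = {
        "dominant": float(((dq > 0) & (dc < 0)).sum() / n),
        "more_effective_more_costly": float(((dq > 0) & (dc >= 0)).sum() / n),
        "less_effective_less_costly": float(((dq <= 0) & (dc < 0)).sum() / n),
        "dominated": float(((dq <= 0) & (dc >= 0)).sum() / n),
    }
    assert abs(sum(out.values()) - 1.0) < 1e-12
    return out


@dataclass
class TornadoEntry:
    """One-way swing of a single parameter."""

    name: str
    low_input: float
    high_input: float
    nmb_low: float
    nmb_high: float
    dq_low: float = 0.0
    dq_high: float = 0.0
    dc_low: float = 0.0
    dc_high: float = 0.0

    @property
    def width(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _clip_to_domain(spec, x: float) -> float:
    if spec.family == "beta":
        return float(np.clip(x, 1e-6, 1 - 1e-6))
    if spec.units == "utility" and spec.mean > 0 and not spec.name.startswith("disutility"):
        return float(np.clip(x, 0.0, 1.0))
    if spec.family in ("gamma", "lognormal") and spec.mean > 0:
        return float(max(x, 1e-9))
    return float(x)


def tornado(
    params: ParameterSet,
    relapse_fit: survival.SurvivalFit | None = None,
    table: LifeTable | None = None,
    reference_wtp: float = 30_000.0,
    drug: str = "eculizumab",
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis on incremental NMB.

    Every uncertain model parameter is set to mean -/+ 1.96 SE (clipped to
    its domain) with all others at their means; the time-to-relapse curve
    enters through its location parameter perturbed by -/+ 1.96 SE from the
    fit covariance.  Entries are sorted by NMB swing width, widest first.
    """
    params, table, relapse_fit = base_case_inputs(params, table, relapse_fit)
    config = params.config

    def outcomes(values, fit):
        rp = survival.cycle_probabilities(fit, config)
        w = run_arm("withdrawal", values, config, table, rp, drug=drug)
        m = run_arm("maintenance", values, config, table, rp, drug=drug)
        dq, dc = w.qalys - m.qalys, w.cost - m.cost
        return dq, dc, reference_wtp * dq - dc

    base_values = params.point_values()
    entries: list[TornadoEntry] = []
    for name, spec in params.specs.items():
        lo = _clip_to_domain(spec, spec.mean - 1.96 * spec.se)
        hi = _clip_to_domain(spec, spec.mean + 1.96 * spec.se)
        if spec.se == 0 or lo == hi:
            dq, dc, nmb = outcomes(base_values, relapse_fit)
            entries.append(TornadoEntry(name, spec.mean, spec.mean, nmb, nmb,
                                        dq, dq, dc, dc))
            continue
        res = {}
        for tag, x in (("low", lo), ("high", hi)):
            vals = dict(base_values)
            vals[name] = x
            res[tag] = outcomes(vals, relapse_fit)
        entries.append(TornadoEntry(
            name, lo, hi,
            nmb_low=res["low"][2], nmb_high=res["high"][2],
            dq_low=res["low"][0], dq_high=res["high"][0],
            dc_low=res["low"][1], dc_high=res["high"][1],
        ))

    # the relapse curve itself: perturb the location parameter of the fit
    names = list(relapse_fit.params)
    loc = names[0] if relapse_fit.family != "lognormal" else "mu_"
    i = names.index(loc)
    se_loc = float(np.sqrt(relapse_fit.covariance[i, i]))
    res = {}
    for tag, delta in (("low", -1.96 * se_loc), ("high", 1.96 * se_loc)):
        p = dict(relapse_fit.params)
        p[loc] = p[loc] + delta if not relapse_fit.positive[i] else p[loc] * np.exp(delta / p[loc])
        fit = survival.SurvivalFit(
            family=relapse_fit.family, params=p, covariance=relapse_fit.covariance,
            loglik=relapse_fit.loglik, n=relapse_fit.n, n_events=relapse_fit.n_events,
        )
        res[tag] = outcomes(base_values, fit)
    entries.append(TornadoEntry(
        "time_to_relapse_location",
        relapse_fit.params[loc] - 1.96 * se_loc, relapse_fit.params[loc] + 1.96 * se_loc,
        nmb_low=res["low"][2], nmb_high=res["high"][2],
        dq_low=res["low"][0], dq_high=res["high"][0],
        dc_low=res["low"][1], dc_high=res["high"][1],
    ))

    entries.sort(key=lambda e: e.width, reverse=True)
    return pd.DataFrame([vars(e) | {"nmb_width": e.width} for e in entries])
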