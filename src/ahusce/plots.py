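"""Publication-style figures: extrapolations, CE plane, CEAC, tornado."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .survival import FAMILIES, SurvivalData, SurvivalFit, kaplan_meier  # noqa: E402


def plot_extrapolations(
    data: SurvivalData,
    fits: dict[str, SurvivalFit],
    horizon_months: float = 960.0,
    ax=None,
):
    """Kaplan-Meier step plus all parametric extrapolations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    km = kaplan_meier(data)
    ax.step(km.survival_function_.index, km.survival_function_.iloc[:, 0],
            where="post", color="black", lw=2, label="Kaplan-Meier")
    t = np.linspace(0.01, horizon_months, 600)
    for fam in FAMILIES:
        if fam in fits:
            ax.plot(t / 12, fits[fam].survival(t), label=fam)
    ax.set_xlabel("years since withdrawal")
    ax.set_ylabel("relapse-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_ce_plane(draws: pd.DataFrame, ax=None):
    """PSA scatter on the cost-effectiveness plane (withdrawal vs maintenance)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    ax.scatter(draws["dq"], draws["dc"] / 1e6, s=4, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (million GBP)")
    return ax


def plot_ceac(curve: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"] / 1000, curve["probability"])
    ax.set_xlabel("willingness to pay (thousand GBP per QALY)")
    ax.set_ylabel("P(withdrawal cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_tornado(entries: pd.DataFrame, top: int = 12, ax=None):
    """Ranked NMB swings, widest at the top."""
    df = entries.head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1))
    base = (df["nmb_low"] + df["nmb_high"]) / 2
    ax.barh(df["name"], (df["nmb_high"] - df["nmb_low"]) / 1e6,
            left=df[["nmb_low", "nmb_high"]].min(axis=1) / 1e6, color="steelblue")
    ax.set_xlabel("incremental NMB swing (million GBP)")
    del base
    return ax
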