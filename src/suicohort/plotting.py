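"""Trend figures: SI/SA prevalence and risk-band shares by school year."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .coding import RISK_LEVELS

__all__ = ["plot_prevalence_trend", "plot_risk_trend"]


def plot_prevalence_trend(trend: pd.DataFrame, path) -> None:
    """Line plot of per-year outcome prevalence.

    ``trend`` is the tidy frame written by the pipeline: columns
    outcome, group (school year), proportion.
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    for outcome, grp in trend.groupby("outcome"):
        grp = grp.sort_values("group")
        ax.plot(grp["group"], 100 * grp["proportion"], marker="o", label=outcome.upper())
    ax.set_ylabel("12-month prevalence (%)")
    ax.set_xlabel("school year")
    ax.legend()
    fig.autofmt_xdate(rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_risk_trend(risk_trend: pd.DataFrame, path) -> None:
    """Line plot of low/moderate/high risk-band shares per school year."""
    fig, ax = plt.subplots(figsize=(7, 4))
    grp = risk_trend.sort_values("group")
    for band in RISK_LEVELS:
        ax.plot(grp["group"], 100 * grp[band], marker="o", label=band)
    ax.set_ylabel("share of students (%)")
    ax.set_xlabel("school year")
    ax.legend(title="risk band")
    fig.autofmt_xdate(rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
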