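"""Minimal plotting helpers for adjustment distributions and condition means."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_adjustment_distribution(adjustments: pd.DataFrame, ax=None, bins=None):
    """Histogram of per-round adjustments s, split by condition."""
    ax = _axes(ax)
    if bins is None:
        bins = np.arange(-0.3, 1.35, 0.05)
    for condition, colour in (("peer", "#e6b800"), ("adult", "#3366cc")):
        sub = adjustments[adjustments["condition"] == condition]
        ax.hist(sub["s"].clip(-0.3, 1.3), bins=bins, alpha=0.55,
                label=condition, color=colour)
    ax.set_xlabel("adjustment s")
    ax.set_ylabel("rounds")
    ax.legend()
    return ax


def plot_condition_means(summaries: pd.DataFrame, ax=None):
    """Bar plot of cohort mean S per condition with +/- 1 SEM."""
    ax = _axes(ax)
    means, sems = [], []
    for col in ("S_peer", "S_adult"):
        vals = summaries[col].dropna()
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)))
    ax.bar(["peer", "adult"], means, yerr=sems, color=["#e6b800", "#3366cc"], capsize=4)
    ax.set_ylabel("mean adjustment S")
    ax.set_ylim(0, 1)
    return ax
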