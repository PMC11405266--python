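"""Simple plot helpers for clock fits, gap distributions and KM curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd


def plot_age_prediction(gap_table: pd.DataFrame, ax=None):
    """Predicted versus chronological age scatter with the identity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(gap_table["age"], gap_table["protage"], s=6, alpha=0.4,
               edgecolors="none")
    lo = min(gap_table["age"].min(), gap_table["protage"].min())
    hi = max(gap_table["age"].max(), gap_table["protage"].max())
    ax.plot([lo, hi], [lo, hi], color="black", lw=1, ls="--")
    ax.set_xlabel("chronological age (years)")
    ax.set_ylabel("protein-predicted age (years)")
    return ax


def plot_gap_distribution(gap_table: pd.DataFrame, ax=None, bins: int = 40):
    """Histogram of the proteomic age gap."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(gap_table["gap"], bins=bins, color="#4477aa")
    ax.axvline(0.0, color="black", lw=1)
    ax.set_xlabel("proteomic age gap (years)")
    ax.set_ylabel("samples")
    return ax


def plot_km_curves(km: pd.DataFrame, endpoint: str | None = None, ax=None):
    """Cumulative incidence curves per gap-decile group, with CI bands."""
    if endpoint is not None:
        km = km[km["endpoint"] == endpoint]
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4))
    for label, grp in km.groupby("group"):
        grp = grp.sort_values("grid")
        ax.step(grp["grid"], grp["incidence"], where="post", label=str(label))
        ax.fill_between(grp["grid"], grp["ci_low"], grp["ci_high"],
                        step="post", alpha=0.2)
    ax.set_xlabel("age at recruitment (years)")
    ax.set_ylabel("cumulative incidence")
    ax.set_ylim(0, 1)
    ax.legend(title="gap decile", fontsize=8)
    return ax
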