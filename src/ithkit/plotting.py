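"""Matplotlib helpers for CCF scatter and per-cluster violin plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt
import pandas as pd

from .subclones import OUTLIER_LABEL

__all__ = ["plot_ccf_scatter", "plot_cluster_violins", "plot_spectrum"]


def plot_ccf_scatter(scatter: pd.DataFrame, sample_a: str, sample_b: str, ax=None):
    """Scatter of per-mutation CCFs in two samples, colored by cluster."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for label, group in scatter.groupby("cluster"):
        if label == OUTLIER_LABEL:
            ax.scatter(group["ccf_a"], group["ccf_b"], s=12, c="lightgrey", label=label)
        else:
            ax.scatter(group["ccf_a"], group["ccf_b"], s=14, label=f"subclone {label}")
    ax.set_xlabel(f"CCF in {sample_a}")
    ax.set_ylabel(f"CCF in {sample_b}")
    ax.set_xlim(-0.02, 1.05)
    ax.set_ylim(-0.02, 1.05)
    ax.legend(fontsize=7, loc="upper left", framealpha=0.6)
    return ax


def plot_cluster_violins(estimates: pd.DataFrame, assignments: pd.Series, ax=None):
    """Violin plot of member CCFs per cluster (both samples pooled per
    mutation, as each mutation carries one CCF per sample)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    merged = estimates.merge(
        assignments.rename("cluster_id"), left_on="mutation_id", right_index=True
    )
    order = sorted(merged["cluster_id"].unique())
    data = [merged.loc[merged["cluster_id"] == c, "ccf_hat"] for c in order]
    ax.violinplot(data, positions=range(len(order)), showmedians=True)
    counts = [len(d) for d in data]
    ax.set_xticks(range(len(order)), [f"{c}\nn={n}" for c, n in zip(order, counts)])
    ax.set_xlabel("subclone cluster")
    ax.set_ylabel("CCF")
    return ax


def plot_spectrum(spectrum: pd.DataFrame, ax=None):
    """Bar chart of six-class substitution fractions per group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    frac_cols = [c for c in spectrum.columns if c.endswith("_frac")]
    spectrum[frac_cols].rename(columns=lambda c: c.removesuffix("_frac")).plot.bar(ax=ax)
    ax.set_ylabel("fraction of SNVs")
    ax.legend(fontsize=7)
    return ax
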