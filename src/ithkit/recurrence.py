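"""Mutated-gene recurrence tables at the sample and patient level.

Only nonsynonymous functional classes count (frameshift/non-frameshift indel,
stop-gain/stop-loss, splicing, nonsynonymous SNV).  A gene counts once per
sample (or once per patient) regardless of how many distinct mutations hit it
there; frequencies are displayed as ``k/N`` with the percentage rounded to the
nearest integer, e.g. a gene mutated in 5 of 12 samples prints "5/12" and 42%.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["NONSYNONYMOUS_CLASSES", "FUNCTIONAL_CLASSES", "recurrence_table", "heatmap_matrix"]

NONSYNONYMOUS_CLASSES = frozenset(
    {
        "frameshift indel",
        "non-frameshift indel",
        "stop-gain",
        "stop-loss",
        "splicing",
        "nonsynonymous SNV",
    }
)
FUNCTIONAL_CLASSES = NONSYNONYMOUS_CLASSES | {"synonymous SNV", "other"}


def _check_classes(mutations: pd.DataFrame) -> pd.DataFrame:
    unknown = set(mutations["functional_class"]) - FUNCTIONAL_CLASSES
    if unknown:
        warnings.warn(f"excluding mutations with unknown functional classes: {sorted(unknown)}")
        mutations = mutations[~mutations["functional_class"].isin(unknown)]
    return mutations


def recurrence_table(mutations: pd.DataFrame, level: str = "sample") -> pd.DataFrame:
    """Gene recurrence across samples or patients.

    Parameters
    ----------
    mutations
        Columns ``gene``, ``functional_class``, ``sample_id`` and (for
        patient level) ``patient_id``.
    level
        ``"sample"`` or ``"patient"``.

    Returns
    -------
    DataFrame with ``gene``, ``count``, ``denominator``, ``frequency``
    (``k/N`` string) and ``percent`` (nearest integer), sorted by count
    descending then gene symbol ascending.
    """
    if level not in ("sample", "patient"):
        raise ValueError(f"level must be 'sample' or 'patient', got {level!r}")
    unit = "sample_id" if level == "sample" else "patient_id"
    mutations = _check_classes(mutations)
    denominator = mutations[unit].nunique()
    nonsyn = mutations[mutations["functional_class"].isin(NONSYNONYMOUS_CLASSES)]
    counts = (
        nonsyn[["gene", unit]]
        .drop_duplicates()
        .groupby("gene")
        .size()
        .rename("count")
        .reset_index()
    )
    counts = counts.sort_values(["count", "gene"], ascending=[False, True], ignore_index=True)
    counts["denominator"] = denominator
    counts["frequency"] = counts["count"].astype(str) + "/" + str(denominator)
    counts["percent"] = (counts["count"] / denominator * 100).round().astype(int)
    return counts


def heatmap_matrix(mutations: pd.DataFrame) -> pd.DataFrame:
    """Genes x samples matrix coding the (first) nonsynonymous mutation class
    per cell, empty string where a gene is not mutated in a sample."""
    mutations = _check_classes(mutations)
    nonsyn = mutations[mutations["functional_class"].isin(NONSYNONYMOUS_CLASSES)]
    if nonsyn.empty:
        return pd.DataFrame()
    mat = nonsyn.pivot_table(
        index="gene",
        columns="sample_id",
        values="functional_class",
        aggfunc="first",
    ).fillna("")
    order = recurrence_table(mutations, level="sample")["gene"]
    return mat.reindex(order)
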