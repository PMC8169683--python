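"""Subclone identification from multi-sample CCF vectors.

Mutations with similar CCF profiles across tumor regions are grouped in two
stages: agglomerative hierarchical clustering (Euclidean distance, average
linkage) cut at a fine height in CCF units, followed by iterative merging of
groups whose per-sample median centers lie within ``merge_threshold`` of each
other.  The second stage is what makes the procedure usable at exome depth:
at ~170x coverage the per-sample CCF sampling noise is sigma ~ 0.08-0.09, so
the final average-linkage merge height inside one true subclone (~1.8-3.5
sigma) overlaps the merge heights between distinct subclones, and any
single-stage cut either shatters real clusters or fuses separate ones.
Fragment centers of a single subclone stay within ~2 sigma, while subclones
worth distinguishing at this depth differ by >= 3 sigma, hence the default
``merge_threshold`` of 0.25; subclones closer than that in CCF space are
below the method's resolution and report as one cluster.

Clusters with fewer than ``min_cluster_size`` members (default 3) are
outliers and excluded from downstream interpretation.  A cluster's CCF in a
sample is the median of its members' CCFs there.

Two biologically meaningful flags are derived from the cluster CCFs:

``ith``
    very low CCF in at least one sample but high CCF in another —
    a sample-private subclone, i.e. clear intratumor heterogeneity.
``driver_candidate``
    CCF strictly above a threshold (default 0.7) in *every* sample — a
    subclone large enough everywhere to plausibly carry driver mutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "SubcloneCluster",
    "cluster_mutations",
    "flag_ith_subclones",
    "flag_driver_subclones",
    "scatter_table",
    "assignments_series",
    "cluster_ccf_frame",
]

DEFAULT_CUT_HEIGHT = 0.15
DEFAULT_MERGE_THRESHOLD = 0.25
DEFAULT_MIN_CLUSTER_SIZE = 3
OUTLIER_LABEL = "outlier"


@dataclass
class SubcloneCluster:
    """One mutation cluster with its per-sample central CCF and flags."""

    cluster_id: int
    members: list[str]
    ccf: pd.Series  # per-sample median CCF of members
    is_outlier: bool = False
    ith: bool = False
    driver_candidate: bool = False

    @property
    def n(self) -> int:
        return len(self.members)


def _merge_close_centers(
    values: np.ndarray, labels: np.ndarray, merge_threshold: float
) -> np.ndarray:
    """Iteratively fuse clusters whose median centers are within threshold,
    closest pair first (ids break ties); centers recomputed after each fuse."""
    labels = labels.copy()
    while True:
        ids = np.unique(labels)
        if len(ids) == 1:
            break
        centers = {i: np.median(values[labels == i], axis=0) for i in ids}
        best = None
        for a, b in itertools.combinations(ids, 2):
            d = float(np.linalg.norm(centers[a] - centers[b]))
            if d < merge_threshold and (best is None or d < best[0]):
                best = (d, a, b)
        if best is None:
            break
        labels[labels == best[2]] = best[1]
    return labels


def _absorb_minor_fragments(
    values: np.ndarray, labels: np.ndarray, absorb_frac: float, absorb_threshold: float
) -> np.ndarray:
    """Fold minor clusters (< absorb_frac of the largest) into the nearest
    larger cluster when their centers lie within absorb_threshold.

    Extreme-tail points of a large cluster can survive the center-merge stage
    as a small satellite sitting 3-4 sigma out; a genuinely distinct subclone
    this close to a major one is below the method's resolution anyway, while
    genuinely small subclones (e.g. sample-private ones) sit far away in CCF
    space and are untouched.
    """
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if len(ids) == 1:
            break
        size = dict(zip(ids, counts))
        cutoff = absorb_frac * counts.max()
        centers = {i: np.median(values[labels == i], axis=0) for i in ids}
        best = None
        for i in ids:
            if size[i] >= cutoff:
                continue
            for j in ids:
                if size[j] <= size[i]:
                    continue
                d = float(np.linalg.norm(centers[i] - centers[j]))
                if d < absorb_threshold and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is None:
            break
        labels[labels == best[1]] = best[2]
    return labels


def cluster_mutations(
    ccfs: pd.DataFrame,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    linkage_method: str = "average",
    absorb_frac: float = 0.15,
    absorb_threshold: float = 0.35,
) -> list[SubcloneCluster]:
    """Two-stage clustering of the rows of a mutations x samples CCF matrix.

    Stage one cuts an average-linkage dendrogram at ``cut_height``; stage two
    merges resulting groups whose median CCF centers are within
    ``merge_threshold`` (set it to 0 to disable), then folds minor satellite
    groups (< ``absorb_frac`` of the largest cluster) into a larger cluster
    whose center is within ``absorb_threshold`` (set ``absorb_frac`` to 0 to
    disable).  Every mutation lands in exactly one cluster; clusters smaller
    than ``min_cluster_size`` are marked outliers.  Returned clusters are
    numbered by decreasing size (ties broken by first member id) starting
    at 0.

    Raises
    ------
    ValueError
        If the matrix is empty.
    """
    if ccfs.empty:
        raise ValueError("empty CCF matrix")
    values = ccfs.to_numpy(dtype=float)
    if len(ccfs) == 1:
        labels = np.array([1])
    else:
        link = hierarchy.linkage(values, method=linkage_method, metric="euclidean")
        labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
        if merge_threshold > 0:
            labels = _merge_close_centers(values, labels, merge_threshold)
        if absorb_frac > 0:
            labels = _absorb_minor_fragments(values, labels, absorb_frac, absorb_threshold)
    clusters: list[SubcloneCluster] = []
    for raw_label in np.unique(labels):
        idx = ccfs.index[labels == raw_label]
        members = list(idx)
        med = ccfs.loc[idx].median(axis=0)
        clusters.append(
            SubcloneCluster(
                cluster_id=-1,
                members=members,
                ccf=med,
                is_outlier=len(members) < min_cluster_size,
            )
        )
    clusters.sort(key=lambda c: (-c.n, str(c.members[0])))
    for new_id, cluster in enumerate(clusters):
        cluster.cluster_id = new_id
    return clusters


def flag_ith_subclones(
    clusters: list[SubcloneCluster], low: float = 0.1, high: float = 0.5
) -> list[SubcloneCluster]:
    """Flag non-outlier clusters whose CCF drops below ``low`` in some sample
    while exceeding ``high`` in another (sample-private subclones)."""
    if not low < high:
        raise ValueError("need low < high")
    for c in clusters:
        c.ith = (not c.is_outlier) and bool(c.ccf.min() < low and c.ccf.max() > high)
    return clusters


def flag_driver_subclones(
    clusters: list[SubcloneCluster], threshold: float = 0.7
) -> list[SubcloneCluster]:
    """Flag non-outlier clusters with CCF strictly above ``threshold`` in
    every sample."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    for c in clusters:
        c.driver_candidate = (not c.is_outlier) and bool((c.ccf > threshold).all())
    return clusters


def assignments_series(clusters: list[SubcloneCluster]) -> pd.Series:
    """mutation id -> cluster id (outlier members keep their cluster id)."""
    mapping = {m: c.cluster_id for c in clusters for m in c.members}
    return pd.Series(mapping, name="cluster_id")


def scatter_table(
    ccfs: pd.DataFrame,
    clusters: list[SubcloneCluster],
    sample_a: str,
    sample_b: str,
) -> pd.DataFrame:
    """Plot-ready two-sample CCF table: one row per mutation with its cluster
    label, outliers labelled ``"outlier"``.

    Raises
    ------
    KeyError
        If either sample is not a column of the matrix.
    """
    for s in (sample_a, sample_b):
        if s not in ccfs.columns:
            raise KeyError(f"unknown sample id: {s}")
    labels = {}
    for c in clusters:
        label = OUTLIER_LABEL if c.is_outlier else str(c.cluster_id)
        for m in c.members:
            labels[m] = label
    out = pd.DataFrame(
        {
            "ccf_a": ccfs[sample_a],
            "ccf_b": ccfs[sample_b],
            "cluster": [labels.get(m, OUTLIER_LABEL) for m in ccfs.index],
        },
        index=ccfs.index,
    )
    out.index.name = "mutation_id"
    return out


def cluster_ccf_frame(clusters: list[SubcloneCluster]) -> pd.DataFrame:
    """Clusters x samples CCF matrix (non-outlier clusters only)."""
    keep = [c for c in clusters if not c.is_outlier]
    if not keep:
        return pd.DataFrame()
    frame = pd.DataFrame({c.cluster_id: c.ccf for c in keep}).T
    frame.index.name = "cluster_id"
    return frame
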