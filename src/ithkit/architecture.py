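"""Enumeration of subclonal architectures consistent with cluster CCFs.

Two subclones can be in a *linear* relationship — the one with smaller CCF
arose inside cells already carrying the larger one — or a *branching*
relationship — they arose in different ancestral cells and occupy disjoint
portions of the tumor.  Over multiple samples these relations constrain the
set of rooted clone trees:

dominance
    an edge parent -> child requires ccf_child(s) <= ccf_parent(s) + eps in
    every sample s;
lineage sum rule
    the children of any node may sum to at most the parent's CCF + eps in
    every sample (a cell subpopulation cannot be split into more than itself).

``enumerate_architectures`` returns every rooted labeled tree over the
clusters satisfying both constraints.  The root is the cluster that dominates
all others; when none does, a virtual root with CCF 1 everywhere is inserted.
Enumeration is exact (recursive parent assignment with early pruning) and
therefore capped at ``max_clusters``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ArchitectureConfig",
    "Architecture",
    "CapacityError",
    "classify_pair",
    "enumerate_architectures",
    "relations_from_tree",
]

VIRTUAL_ROOT = "virtual_root"


class CapacityError(RuntimeError):
    """Raised when the cluster count exceeds the exact-enumeration cap."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Tolerance and size cap for architecture enumeration."""

    epsilon: float = 0.05
    max_clusters: int = 10

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class Architecture:
    """A rooted clone tree given as a child -> parent mapping."""

    parent: tuple[tuple[Hashable, Hashable], ...]  # canonical sorted items
    root: Hashable
    has_virtual_root: bool = False

    @classmethod
    def from_mapping(
        cls, parent: dict[Hashable, Hashable], root: Hashable, has_virtual_root: bool = False
    ) -> "Architecture":
        items = tuple(sorted(parent.items(), key=lambda kv: str(kv[0])))
        return cls(parent=items, root=root, has_virtual_root=has_virtual_root)

    @property
    def parent_map(self) -> dict[Hashable, Hashable]:
        return dict(self.parent)

    def nodes(self) -> list[Hashable]:
        ns = {self.root}
        for c, p in self.parent:
            ns.add(c)
            ns.add(p)
        return sorted(ns, key=str)

    def children(self, node: Hashable) -> list[Hashable]:
        return [c for c, p in self.parent if p == node]

    def ancestors(self, node: Hashable) -> set[Hashable]:
        pm = self.parent_map
        out = set()
        while node in pm:
            node = pm[node]
            out.add(node)
        return out

    def to_newick(self) -> str:
        """Topology-only Newick string with cluster ids as labels."""

        def sub(node: Hashable) -> str:
            kids = sorted(self.children(node), key=str)
            if not kids:
                return str(node)
            return "(" + ",".join(sub(k) for k in kids) + ")" + str(node)

        return sub(self.root) + ";"


def classify_pair(
    ccf_a: Iterable[float],
    ccf_b: Iterable[float],
    config: ArchitectureConfig | None = None,
) -> str:
    """Possible relation between two subclones from their per-sample CCFs.

    Returns one of ``a_parent_of_b_possible``, ``b_parent_of_a_possible``,
    ``branching_only`` (neither dominates) or ``ambiguous`` (both dominate
    within tolerance).

    Raises
    ------
    ValueError
        If the CCF vectors have different lengths (mismatched sample sets).
    """
    config = config or ArchitectureConfig()
    a = np.asarray(list(ccf_a), dtype=float)
    b = np.asarray(list(ccf_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("CCF vectors must cover the same samples")
    eps = config.epsilon
    a_dom = bool((a >= b - eps).all())
    b_dom = bool((b >= a - eps).all())
    if a_dom and b_dom:
        return "ambiguous"
    if a_dom:
        return "a_parent_of_b_possible"
    if b_dom:
        return "b_parent_of_a_possible"
    return "branching_only"


def _dominates(ccfs: pd.DataFrame, a: Hashable, b: Hashable, eps: float) -> bool:
    return bool((ccfs.loc[a].to_numpy() >= ccfs.loc[b].to_numpy() - eps).all())


def _select_root(ccfs: pd.DataFrame, eps: float) -> Hashable | None:
    """The cluster dominating all others; largest total CCF breaks ties."""
    candidates = [
        r for r in ccfs.index if all(_dominates(ccfs, r, o, eps) for o in ccfs.index if o != r)
    ]
    if not candidates:
        return None
    totals = ccfs.loc[candidates].sum(axis=1)
    best = totals.max()
    for r in candidates:  # index order breaks exact ties
        if totals[r] == best:
            return r
    return None  # pragma: no cover


def enumerate_architectures(
    ccfs: pd.DataFrame, config: ArchitectureConfig | None = None
) -> list[Architecture]:
    """All rooted trees over the clusters compatible with the CCF constraints.

    Parameters
    ----------
    ccfs
        Clusters x samples CCF matrix (non-outlier clusters).
    config
        Tolerance ``epsilon`` and the ``max_clusters`` enumeration cap.

    Returns
    -------
    Deterministically ordered list of :class:`Architecture`.  If no cluster
    dominates all others a virtual root (CCF 1 everywhere) is added and
    reported via ``has_virtual_root``.

    Raises
    ------
    CapacityError
        If there are more than ``max_clusters`` clusters.
    ValueError
        If the matrix is empty.
    """
    config = config or ArchitectureConfig()
    if ccfs.empty:
        raise ValueError("no clusters to arrange")
    if len(ccfs) > config.max_clusters:
        raise CapacityError(
            f"{len(ccfs)} clusters exceed max_clusters={config.max_clusters}; "
            "enumeration is exponential — raise the cap explicitly if intended"
        )
    eps = config.epsilon
    root = _select_root(ccfs, eps)
    virtual = root is None
    work = ccfs.copy()
    if virtual:
        root = VIRTUAL_ROOT
        work.loc[VIRTUAL_ROOT] = 1.0

    nodes = [n for n in work.index if n != root]
    all_nodes = [root, *nodes]
    values = {n: work.loc[n].to_numpy(dtype=float) for n in all_nodes}
    # feasible parents per child under edge dominance
    allowed = {
        c: [p for p in all_nodes if p != c and (values[c] <= values[p] + eps).all()]
        for c in nodes
    }

    results: list[Architecture] = []
    child_sum: dict[Hashable, np.ndarray] = {n: np.zeros(work.shape[1]) for n in all_nodes}
    parent: dict[Hashable, Hashable] = {}

    def assign(i: int) -> None:
        if i == len(nodes):
            if _reaches_root(parent, root, nodes):
                results.append(Architecture.from_mapping(dict(parent), root, virtual))
            return
        child = nodes[i]
        for p in allowed[child]:
            new_sum = child_sum[p] + values[child]
            if (new_sum <= values[p] + eps).all():
                parent[child] = p
                child_sum[p] = new_sum
                assign(i + 1)
                child_sum[p] = new_sum - values[child]
                del parent[child]

    assign(0)
    results.sort(key=lambda a: a.parent)
    return results


def _reaches_root(parent: dict, root: Hashable, nodes: list) -> bool:
    for n in nodes:
        seen = set()
        cur = n
        while cur != root:
            if cur in seen or cur not in parent:
                return False
            seen.add(cur)
            cur = parent[cur]
    return True


def relations_from_tree(arch: Architecture, include_virtual_root: bool = False) -> pd.DataFrame:
    """Pairwise linear/branching relations implied by one architecture.

    Ancestor-descendant pairs are *linear*; incomparable pairs are
    *branching*.  The virtual root, when present, is excluded by default.
    """
    nodes = [
        n
        for n in arch.nodes()
        if include_virtual_root or not (arch.has_virtual_root and n == arch.root)
    ]
    rows = []
    for a, b in combinations(nodes, 2):
        if a in arch.ancestors(b) or b in arch.ancestors(a):
            rel = "linear"
        else:
            rel = "branching"
        rows.append((a, b, rel))
    return pd.DataFrame(rows, columns=["subclone_a", "subclone_b", "relation"])
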