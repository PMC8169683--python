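"""Architecture enumeration: pair relations, constraint checks, oracle parity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ithkit.architecture import (
    Architecture,
    ArchitectureConfig,
    CapacityError,
    VIRTUAL_ROOT,
    classify_pair,
    enumerate_architectures,
    relations_from_tree,
)

EPS0 = ArchitectureConfig(epsilon=0.0)


# ---------------------------------------------------------------- oracle ----
def oracle_enumerate(ccfs: pd.DataFrame, eps: float) -> set[frozenset]:
    """Exhaustive independent generator: test every parent assignment of every
    node against the dominance and sum constraints by direct re-statement."""
    work = ccfs.copy()
    dominators = []
    for r in work.index:
        if all(
            (work.loc[r] >= work.loc[o] - eps).all() for o in work.index if o != r
        ):
            dominators.append(r)
    if dominators:
        totals = {r: work.loc[r].sum() for r in dominators}
        best = max(totals.values())
        root = next(r for r in work.index if r in dominators and totals[r] == best)
    else:
        root = VIRTUAL_ROOT
        work.loc[VIRTUAL_ROOT] = 1.0
    nodes = [n for n in work.index if n != root]
    found = set()
    for parents in itertools.product(list(work.index), repeat=len(nodes)):
        pm = {c: p for c, p in zip(nodes, parents)}
        if any(c == p for c, p in pm.items()):
            continue
        # connectivity / acyclicity: every node must reach the root
        ok = True
        for n in nodes:
            cur, seen = n, set()
            while cur != root:
                if cur in seen or cur not in pm:
                    ok = False
                    break
                seen.add(cur)
                cur = pm[cur]
            if not ok:
                break
        if not ok:
            continue
        # edge dominance
        if any((work.loc[c] > work.loc[p] + eps).any() for c, p in pm.items()):
            continue
        # lineage sum rule
        for p in work.index:
            kids = [c for c, q in pm.items() if q == p]
            if kids and (work.loc[kids].sum() > work.loc[p] + eps).any():
                ok = False
                break
        if ok:
            found.add(frozenset(pm.items()))
    return found


def _ccfs(rows: dict[str, tuple[float, ...]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestClassifyPair:
    def test_strict_dominance(self):
        assert classify_pair((0.9, 0.8), (0.4, 0.3)) == "a_parent_of_b_possible"
        assert classify_pair((0.4, 0.3), (0.9, 0.8)) == "b_parent_of_a_possible"

    def test_crossing_ccfs_branch(self):
        assert classify_pair((0.4, 0.3), (0.3, 0.45)) == "branching_only"

    def test_symmetric_within_tolerance_ambiguous(self):
        assert classify_pair((0.5, 0.5), (0.5, 0.5)) == "ambiguous"

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError):
            classify_pair((0.5, 0.5), (0.5,))


class TestEnumerate:
    def test_worked_chain_and_star(self):
        ccfs = _ccfs({"R": (1.0, 1.0), "B": (0.6, 0.6), "C": (0.3, 0.3)})
        archs = enumerate_architectures(ccfs, EPS0)
        parent_maps = [a.parent_map for a in archs]
        assert len(archs) == 2
        assert {"B": "R", "C": "B"} in parent_maps  # chain R->B->C
        assert {"B": "R", "C": "R"} in parent_maps  # star
        assert {"B": "C", "C": "R"} not in parent_maps  # B not <= C

    def test_sum_rule_rejects_star_of_equal_children(self):
        ccfs = _ccfs({"R": (1.0, 1.0), "B": (0.6, 0.6), "C": (0.6, 0.6)})
        archs = enumerate_architectures(ccfs, EPS0)
        assert len(archs) == 2
        assert {"B": "R", "C": "R"} not in [a.parent_map for a in archs]

    def test_single_cluster_trivial_tree(self):
        archs = enumerate_architectures(_ccfs({"A": (0.8, 0.9)}), EPS0)
        assert len(archs) == 1 and archs[0].parent == ()

    def test_virtual_root_added_when_no_dominator(self):
        ccfs = _ccfs({"A": (0.6, 0.1), "B": (0.1, 0.6)})
        archs = enumerate_architectures(ccfs, EPS0)
        assert all(a.has_virtual_root for a in archs)
        assert len(archs) == 1
        assert archs[0].parent_map == {"A": VIRTUAL_ROOT, "B": VIRTUAL_ROOT}

    def test_capacity_cap(self):
        ccfs = pd.DataFrame(np.full((11, 2), 0.5), index=[f"c{i}" for i in range(11)])
        with pytest.raises(CapacityError):
            enumerate_architectures(ccfs, ArchitectureConfig())

    def test_deterministic_order(self):
        ccfs = _ccfs({"R": (1.0, 1.0), "B": (0.6, 0.6), "C": (0.3, 0.3)})
        a = [x.parent for x in enumerate_architectures(ccfs, EPS0)]
        b = [x.parent for x in enumerate_architectures(ccfs, EPS0)]
        assert a == b

    def test_matches_oracle_on_random_instances(self, rng):
        eps = 0.05
        for _ in range(100):
            k = int(rng.integers(2, 6))
            n_samples = int(rng.integers(1, 4))
            vals = rng.uniform(0, 1, size=(k, n_samples)).round(2)
            if rng.random() < 0.5:
                vals[0] = 1.0  # truncal row
            ccfs = pd.DataFrame(vals, index=[f"c{i}" for i in range(k)])
            got = {frozenset(a.parent) for a in enumerate_architectures(ccfs, ArchitectureConfig(eps))}
            assert got == oracle_enumerate(ccfs, eps)

    def test_every_architecture_passes_independent_validation(self, rng):
        for seed in range(20):
            local = np.random.default_rng(seed)
            vals = local.uniform(0, 1, size=(4, 2))
            vals[0] = 1.0
            ccfs = pd.DataFrame(vals, index=list("abcd"))
            for arch in enumerate_architectures(ccfs, ArchitectureConfig(0.05)):
                _validate_architecture(arch, ccfs, 0.05)

    def test_epsilon_monotonicity(self, rng):
        for seed in range(20):
            local = np.random.default_rng(seed)
            vals = local.uniform(0, 1, size=(4, 2))
            vals[0] = 1.0  # stable root across tolerances
            ccfs = pd.DataFrame(vals, index=list("abcd"))
            small = {a.parent for a in enumerate_architectures(ccfs, ArchitectureConfig(0.02))}
            large = {a.parent for a in enumerate_architectures(ccfs, ArchitectureConfig(0.1))}
            assert small <= large


def _validate_architecture(arch: Architecture, ccfs: pd.DataFrame, eps: float) -> None:
    work = ccfs.copy()
    if arch.has_virtual_root:
        work.loc[arch.root] = 1.0
    pm = arch.parent_map
    nodes = arch.nodes()
    assert set(pm) == set(nodes) - {arch.root}
    for n in pm:  # reaches root without revisiting
        cur, seen = n, set()
        while cur != arch.root:
            assert cur not in seen
            seen.add(cur)
            cur = pm[cur]
    for c, p in pm.items():
        assert (work.loc[c] <= work.loc[p] + eps).all()
    for p in nodes:
        kids = arch.children(p)
        if kids:
            assert (work.loc[kids].sum() <= work.loc[p] + eps).all()


def _relation(arch: Architecture, a, b) -> str:
    tab = relations_from_tree(arch)
    hit = tab[
        ((tab["subclone_a"] == a) & (tab["subclone_b"] == b))
        | ((tab["subclone_a"] == b) & (tab["subclone_b"] == a))
    ]
    assert len(hit) == 1
    return hit["relation"].iloc[0]


class TestRelations:
    def test_chain_all_linear(self):
        arch = Architecture.from_mapping({3: 9, 5: 3}, root=9)
        assert _relation(arch, 9, 3) == "linear"
        assert _relation(arch, 3, 5) == "linear"
        assert _relation(arch, 9, 5) == "linear"

    def test_star_siblings_branch(self):
        arch = Architecture.from_mapping({"x": "r", "y": "r"}, root="r")
        assert _relation(arch, "x", "y") == "branching"

    def test_mixed_topology(self):
        arch = Architecture.from_mapping({3: 9, 1: 9, 5: 3}, root=9)
        assert _relation(arch, 3, 1) == "branching"
        assert _relation(arch, 5, 1) == "branching"
        assert _relation(arch, 3, 5) == "linear"

    def test_virtual_root_excluded(self):
        arch = Architecture.from_mapping(
            {"a": VIRTUAL_ROOT, "b": VIRTUAL_ROOT}, root=VIRTUAL_ROOT, has_virtual_root=True
        )
        rel = relations_from_tree(arch)
        assert VIRTUAL_ROOT not in set(rel["subclone_a"]) | set(rel["subclone_b"])


def test_newick_topology():
    arch = Architecture.from_mapping({"b": "a", "c": "a", "d": "b"}, root="a")
    assert arch.to_newick() == "((d)b,c)a;"
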