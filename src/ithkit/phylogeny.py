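"""Two-sample phylogeny from shared and private mutations.

For a pair of tumor regions the mutations partition into the *trunk* (present
in both), and two *private* branch sets (present in exactly one).  The tree is
rooted at the germline: root --trunk--> internal node --> two sample leaves,
with branch lengths equal to the mutation counts, so trunk and branch lengths
are proportional to the number of corresponding mutations.

Presence is CCF (or VAF) strictly above a threshold, which defaults to the
0.05 allele-fraction floor of the somatic filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PhyloPartition", "PhyloTree", "partition_mutations", "build_tree"]

DEFAULT_PRESENCE_THRESHOLD = 0.05


@dataclass(frozen=True)
class PhyloPartition:
    """Trunk/private/excluded mutation sets for a sample pair."""

    sample_a: str
    sample_b: str
    trunk: tuple[str, ...]
    private_a: tuple[str, ...]
    private_b: tuple[str, ...]
    excluded: tuple[str, ...]
    presence_threshold: float

    @property
    def n_total(self) -> int:
        return len(self.trunk) + len(self.private_a) + len(self.private_b) + len(self.excluded)


@dataclass(frozen=True)
class PhyloTree:
    """Three-branch mutation-count tree for one sample pair."""

    sample_a: str
    sample_b: str
    trunk_length: int
    branch_a_length: int
    branch_b_length: int

    def to_newick(self) -> str:
        return (
            f"({self.sample_a}:{self.branch_a_length},"
            f"{self.sample_b}:{self.branch_b_length}):{self.trunk_length};"
        )

    def branch_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "branch": ["trunk", self.sample_a, self.sample_b],
                "mutation_count": [self.trunk_length, self.branch_a_length, self.branch_b_length],
            }
        )


def partition_mutations(
    ccfs: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> PhyloPartition:
    """Split mutations into trunk / private-a / private-b / excluded.

    A mutation is present in a sample iff its value (CCF, or VAF when the
    matrix holds VAFs) exceeds ``presence_threshold`` there; mutations absent
    from both samples are excluded but counted.

    Raises
    ------
    KeyError
        If a requested sample is not a column of the matrix.
    """
    for s in (sample_a, sample_b):
        if s not in ccfs.columns:
            raise KeyError(f"unknown sample id: {s}")
    if not 0 < presence_threshold < 1:
        raise ValueError("presence_threshold must be in (0, 1)")
    in_a = ccfs[sample_a] > presence_threshold
    in_b = ccfs[sample_b] > presence_threshold
    return PhyloPartition(
        sample_a=sample_a,
        sample_b=sample_b,
        trunk=tuple(ccfs.index[in_a & in_b]),
        private_a=tuple(ccfs.index[in_a & ~in_b]),
        private_b=tuple(ccfs.index[~in_a & in_b]),
        excluded=tuple(ccfs.index[~in_a & ~in_b]),
        presence_threshold=presence_threshold,
    )


def build_tree(partition: PhyloPartition) -> PhyloTree:
    """Mutation-count tree for the partition; zero-length branches are kept."""
    return PhyloTree(
        sample_a=partition.sample_a,
        sample_b=partition.sample_b,
        trunk_length=len(partition.trunk),
        branch_a_length=len(partition.private_a),
        branch_b_length=len(partition.private_b),
    )
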