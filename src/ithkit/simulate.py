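"""Forward simulator for multi-region tumor exome datasets.

Generates, from a known clone tree, everything the analysis stages consume:
per-mutation/per-sample read counts (PyClone-style observation table),
tumor- and normal-role variant records with quality annotations, synthetic
gene/functional-class labels, and low-allele-fraction FFPE-like artifacts
present in both tissue roles.  The ground truth (tree, CCFs, assignments,
multiplicities, artifact flags) is returned alongside so that recovery can be
measured exactly.

The defaults emulate a small FFPE breast-tumor exome study: two tumor regions
per patient, ~170x mean coverage, purity 0.8, C>T-dominated substitution
spectrum, and ~5% injected artifacts with allele fractions in (0.05, 0.1].

Clone CCFs are built by stick-breaking: each node's children receive a
Dirichlet-weighted share of a fraction of the parent's CCF, so the lineage sum
rule (children's CCFs sum to at most the parent's, in every sample) holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SUBSTITUTION_CLASSES

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_clone_tree",
    "simulate_ccf_matrix",
    "simulate_read_counts",
    "inject_ffpe_artifacts",
    "simulate_patient",
]

# breast-exome-like six-class weights, C>T transitions dominant
DEFAULT_SPECTRUM_WEIGHTS = {
    "C>A": 0.08,
    "C>G": 0.12,
    "C>T": 0.55,
    "T>A": 0.07,
    "T>C": 0.13,
    "T>G": 0.05,
}

# SNV-consistent functional classes for the synthetic gene annotation
_FUNCTIONAL_CLASSES = ("nonsynonymous SNV", "synonymous SNV", "stop-gain", "stop-loss", "splicing")
_FUNCTIONAL_WEIGHTS = (0.72, 0.20, 0.05, 0.01, 0.02)

_PYR_CLASS_ALLELES = {c: (c[0], c[2]) for c in SUBSTITUTION_CLASSES}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated patient."""

    n_samples: int = 2
    mean_depth: float = 170.0
    purity_per_sample: tuple[float, ...] | float = 0.8
    n_clusters: int = 4
    mutations_per_cluster: int = 40
    artifact_rate: float = 0.05
    artifact_af_range: tuple[float, float] = (0.05, 0.1)
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS)
    )
    private_subclone_prob: float = 0.3
    cna_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        purities = self.purities()
        if not all(0.0 < p <= 1.0 for p in purities):
            raise ValueError(f"purity must be in (0, 1]: {purities}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")
        lo, hi = self.artifact_af_range
        if not (0.0 < lo < hi <= 0.1):
            raise ValueError("artifact_af_range must be a non-empty interval within (0, 0.1]")
        total = sum(self.spectrum_weights.get(c, 0.0) for c in SUBSTITUTION_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"spectrum_weights must sum to 1, got {total}")

    def purities(self) -> tuple[float, ...]:
        if isinstance(self.purity_per_sample, (int, float)):
            return (float(self.purity_per_sample),) * self.n_samples
        if len(self.purity_per_sample) != self.n_samples:
            raise ValueError("purity_per_sample length must equal n_samples")
        return tuple(float(p) for p in self.purity_per_sample)

    def sample_ids(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_samples)]


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``clone_tree`` maps each non-root cluster to its parent; ``ccf_matrix`` is
    clusters x samples; the remaining mappings are keyed by mutation id.
    """

    clone_tree: dict[int, int]
    ccf_matrix: pd.DataFrame
    mutation_assignments: dict[str, int] = field(default_factory=dict)
    artifact_flags: dict[str, bool] = field(default_factory=dict)
    per_mutation_copy_state: dict[str, tuple[int, int]] = field(default_factory=dict)
    multiplicities: dict[str, int] = field(default_factory=dict)

    def children(self, node: int) -> list[int]:
        return sorted(c for c, p in self.clone_tree.items() if p == node)

    def validate(self, atol: float = 1e-12) -> None:
        mat = self.ccf_matrix
        if not np.allclose(mat.loc[0], 1.0):
            raise AssertionError("root CCF must be 1.0 in every sample")
        for node in mat.index:
            kids = self.children(node)
            if kids and not (mat.loc[kids].sum() <= mat.loc[node] + atol).all():
                raise AssertionError(f"lineage sum rule violated at node {node}")


@dataclass
class SimDataset:
    """Bundle of truth, observation table and variant records for one patient."""

    config: SimConfig
    truth: SimTruth
    observations: pd.DataFrame
    variants: pd.DataFrame

    @property
    def tumor_variants(self) -> pd.DataFrame:
        return self.variants[self.variants["role"] == "tumor"]

    @property
    def normal_variants(self) -> pd.DataFrame:
        return self.variants[self.variants["role"] == "normal"]


def simulate_clone_tree(n_clusters: int, seed: int) -> dict[int, int]:
    """Random rooted tree on clusters 0..n_clusters-1, node 0 the root.

    Every non-root node receives a uniformly chosen parent with a smaller id,
    which makes the result acyclic and single-rooted by construction.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    return {child: int(rng.integers(0, child)) for child in range(1, n_clusters)}


def simulate_ccf_matrix(
    tree: dict[int, int],
    n_samples: int,
    seed: int,
    private_subclone_prob: float = 0.3,
    retained_fraction: float = 0.25,
) -> pd.DataFrame:
    """Stick-breaking CCFs per cluster and sample.

    The root has CCF 1.0 everywhere.  In each sample, a node keeps
    ``retained_fraction`` (in expectation, Beta-distributed) of its CCF for
    cells carrying none of the child mutations and splits the rest among its
    children by a flat Dirichlet draw, so children never exceed the parent in
    aggregate.  With probability ``private_subclone_prob`` a non-root cluster
    is zeroed in one randomly chosen sample, creating the sample-private
    subclones that constitute intratumor heterogeneity.
    """
    nodes = sorted({0, *tree.keys(), *tree.values()})
    for child, parent in tree.items():
        if parent >= child:
            raise ValueError("tree must map each child to a smaller-id parent")
    rng = np.random.default_rng(seed)
    samples = [f"T{i + 1}" for i in range(n_samples)]
    mat = pd.DataFrame(0.0, index=nodes, columns=samples)
    mat.loc[0] = 1.0
    children = {n: sorted(c for c, p in tree.items() if p == n) for n in nodes}
    for s in samples:
        for node in nodes:  # ascending ids: parents precede children
            kids = children[node]
            if not kids:
                continue
            keep = rng.beta(1.0, 1.0 / retained_fraction - 1.0)
            shares = rng.dirichlet(np.ones(len(kids))) * (1.0 - keep)
            mat.loc[kids, s] = shares * mat.at[node, s]
    for node in nodes:
        if node != 0 and rng.random() < private_subclone_prob:
            zero_sample = samples[int(rng.integers(0, n_samples))]
            # zero the whole subtree below it too, preserving the sum rule
            stack = [node]
            while stack:
                cur = stack.pop()
                mat.at[cur, zero_sample] = 0.0
                stack.extend(children[cur])
    return mat


def _draw_alleles(rng: np.random.Generator, weights: dict[str, float]) -> tuple[str, str]:
    classes = list(SUBSTITUTION_CLASSES)
    probs = np.array([weights[c] for c in classes])
    cls = classes[int(rng.choice(len(classes), p=probs / probs.sum()))]
    ref, alt = _PYR_CLASS_ALLELES[cls]
    if rng.random() < 0.5:  # report on the purine strand half the time
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


_CNA_STATES = [(2, 1), (2, 0), (2, 2), (3, 1)]


def simulate_read_counts(
    truth: SimTruth, config: SimConfig, gene_pool_size: int = 60
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw read counts for every mutation in every sample.

    Depth is Poisson(mean_depth); the variant count is binomial with expected
    VAF ``rho * m * CCF / (rho * C_t + (1 - rho) * 2)`` where the multiplicity
    ``m`` is drawn uniformly from {1..major_cn} and recorded in the truth.
    Matched-normal records carry expected VAF 0.  Returns the PyClone-style
    observation table and the long-format variant-record table (tumor and
    normal roles, with synthetic gene/functional-class annotation).
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = list(truth.ccf_matrix.columns)
    purities = dict(zip(samples, config.purities()))
    clusters = list(truth.ccf_matrix.index)

    mut_ids = [
        f"m{i:04d}"
        for i in range(len(clusters) * config.mutations_per_cluster)
    ]
    assignments = {
        mid: clusters[i // config.mutations_per_cluster] for i, mid in enumerate(mut_ids)
    }
    truth.mutation_assignments.update(assignments)

    genes = [f"G{i:03d}" for i in range(gene_pool_size)]
    obs_rows, var_rows = [], []
    for i, mid in enumerate(mut_ids):
        cluster = assignments[mid]
        if rng.random() < config.cna_rate:
            major, minor = _CNA_STATES[int(rng.integers(0, len(_CNA_STATES)))]
        else:
            major, minor = 1, 1
        truth.per_mutation_copy_state[mid] = (major, minor)
        m = int(rng.integers(1, major + 1))
        truth.multiplicities[mid] = m
        truth.artifact_flags[mid] = False
        total_cn = major + minor

        chrom = str(1 + i % 22)
        pos = 1_000_000 + 1_000 * i
        ref, alt = _draw_alleles(rng, config.spectrum_weights)
        gene = genes[int(rng.integers(0, gene_pool_size))]
        func = _FUNCTIONAL_CLASSES[
            int(rng.choice(len(_FUNCTIONAL_CLASSES), p=np.array(_FUNCTIONAL_WEIGHTS)))
        ]

        normal_afs = {}
        for s in samples:
            rho = purities[s]
            ccf = float(truth.ccf_matrix.at[cluster, s])
            evaf = (rho * m * ccf) / (rho * total_cn + (1.0 - rho) * 2.0)
            if evaf > 1.0:
                raise RuntimeError(f"expected VAF {evaf} > 1 for {mid} in {s}")
            depth = max(int(rng.poisson(config.mean_depth)), 1)
            var = int(rng.binomial(depth, evaf))
            obs_rows.append(
                (mid, s, depth - var, var, 2, minor, major)
            )
            n_depth = max(int(rng.poisson(config.mean_depth)), 1)
            normal_afs[s] = 0.0
            var_rows.append(
                dict(
                    record_id=f"{mid}:{s}:tumor",
                    mutation_id=mid,
                    sample_id=s,
                    role="tumor",
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    depth=depth,
                    alt_count=var,
                    af=var / depth,
                    gq=99,
                    vqsr=90.0,
                    in_1000g=False,
                    in_esp=False,
                    in_segdup=False,
                    is_multiallelic=False,
                    matched_normal_af=0.0,
                    gene=gene,
                    functional_class=func,
                )
            )
            var_rows.append(
                dict(
                    record_id=f"{mid}:{s}:normal",
                    mutation_id=mid,
                    sample_id=f"N{s[1:]}",
                    role="normal",
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    depth=n_depth,
                    alt_count=0,
                    af=0.0,
                    gq=99,
                    vqsr=90.0,
                    in_1000g=False,
                    in_esp=False,
                    in_segdup=False,
                    is_multiallelic=False,
                    matched_normal_af=np.nan,
                    gene=gene,
                    functional_class=func,
                )
            )
    observations = pd.DataFrame(
        obs_rows,
        columns=[
            "mutation_id",
            "sample_id",
            "ref_counts",
            "var_counts",
            "normal_cn",
            "minor_cn",
            "major_cn",
        ],
    )
    variants = pd.DataFrame(var_rows).set_index("record_id")
    return observations, variants


def inject_ffpe_artifacts(
    variants: pd.DataFrame, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """Append FFPE-like artifact records present in both tissue roles.

    The number of artifacts is Binomial(n_true_mutations, artifact_rate).
    Each artifact gets, independently per role, an allele fraction drawn
    uniformly from ``artifact_af_range`` and an alt count of round(AF*depth),
    so the realized AF stays inside the configured range.  The substitution is
    C>T (or its purine-strand mirror G>A) with probability 0.9, mimicking
    cytosine-deamination chemistry.
    """
    lo, hi = config.artifact_af_range
    if not lo < hi:
        raise ValueError("empty artifact_af_range")
    rng = np.random.default_rng(seed)
    true_ids = variants["mutation_id"].unique()
    n_artifacts = int(rng.binomial(len(true_ids), config.artifact_rate))
    flags: dict[str, bool] = {}
    if n_artifacts == 0 or config.artifact_rate == 0:
        return variants, flags

    samples = sorted(variants.loc[variants["role"] == "tumor", "sample_id"].unique())
    rows = []
    for k in range(n_artifacts):
        aid = f"a{k:04d}"
        flags[aid] = True
        chrom = str(1 + int(rng.integers(0, 22)))
        pos = 50_000_000 + 1_000 * k
        if rng.random() < 0.9:
            ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
        else:
            classes = [c for c in SUBSTITUTION_CLASSES if c != "C>T"]
            cls = classes[int(rng.integers(0, len(classes)))]
            ref, alt = _PYR_CLASS_ALLELES[cls]
        for s in samples:
            af_t = float(rng.uniform(lo, hi))
            af_n = float(rng.uniform(lo, hi))
            d_t = max(int(rng.poisson(config.mean_depth)), 1)
            d_n = max(int(rng.poisson(config.mean_depth)), 1)
            alt_t = max(int(round(af_t * d_t)), 1)
            alt_n = max(int(round(af_n * d_n)), 1)
            common = dict(
                mutation_id=aid,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gq=99,
                vqsr=90.0,
                in_1000g=False,
                in_esp=False,
                in_segdup=False,
                is_multiallelic=False,
                gene="ARTIFACT",
                functional_class="nonsynonymous SNV",
            )
            rows.append(
                dict(
                    record_id=f"{aid}:{s}:tumor",
                    sample_id=s,
                    role="tumor",
                    depth=d_t,
                    alt_count=alt_t,
                    af=alt_t / d_t,
                    matched_normal_af=alt_n / d_n,
                    **common,
                )
            )
            rows.append(
                dict(
                    record_id=f"{aid}:{s}:normal",
                    sample_id=f"N{s[1:]}",
                    role="normal",
                    depth=d_n,
                    alt_count=alt_n,
                    af=alt_n / d_n,
                    matched_normal_af=np.nan,
                    **common,
                )
            )
    artifact_df = pd.DataFrame(rows).set_index("record_id")
    return pd.concat([variants, artifact_df]), flags


def simulate_patient(config: SimConfig) -> SimDataset:
    """Run the full forward model for one patient under ``config``."""
    tree = simulate_clone_tree(config.n_clusters, config.seed)
    ccfs = simulate_ccf_matrix(
        tree, config.n_samples, config.seed, private_subclone_prob=config.private_subclone_prob
    )
    truth = SimTruth(clone_tree=tree, ccf_matrix=ccfs)
    observations, variants = simulate_read_counts(truth, config)
    variants, artifact_flags = inject_ffpe_artifacts(variants, config, config.seed + 2)
    truth.artifact_flags.update(artifact_flags)
    truth.validate()
    return SimDataset(config=config, truth=truth, observations=observations, variants=variants)
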