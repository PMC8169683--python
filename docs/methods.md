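# Methods

`ithkit` reconstructs intratumor heterogeneity from multi-region tumor exome
data: it filters variant calls, screens for FFPE artifacts, summarizes
substitution spectra and gene recurrence, estimates per-mutation cancer cell
fractions (CCFs), groups mutations into subclones, enumerates the clone trees
consistent with the subclone CCFs, and builds a two-sample mutation-count
phylogeny. Everything is exercised against a forward simulator with known
ground truth; this note records the models, the defaults and why, and what
the simulator does and does not capture.

## Variant filtering and swap QC

Somatic calls (tumor role) survive iff read depth > 25, mutant allele
fraction (AF) > 0.05, matched-normal AF < 0.01 (when a matched normal
exists), and the site is in neither the 1000 Genomes nor the Exome Sequencing
Project catalogs. Germline calls (normal role) survive iff depth ≥ 50,
genotype quality ≥ 30, 0.3 ≤ AF ≤ 0.7, not multi-allelic, VQSR tranche score
≤ 97.00, and outside segmental duplications. Comparison directions are exact:
somatic thresholds are strict, germline boundaries inclusive. AF is
`alt_count/depth` when not supplied; depth-0 records fail depth criteria
rather than erroring. Population-catalog membership and VQSR scores are
consumed as input columns — this package never queries external databases or
fits recalibration models.

The swap QC asks whether the pipeline would call "somatic" mutations from the
FFPE *normal* block: the somatic cascade is re-run with tumor and normal
roles exchanged, and survivors are declared artifactual. By default the
cross-sample matched-normal criterion is **not** applied in swap mode. An
FFPE deamination artifact typically appears at low AF in both blocks, so
conditioning on the (swapped) matched sample's AF would veto exactly the
shared artifacts the screen exists to reveal; `use_matched_normal=True`
restores the fully symmetric variant. Artifact calls are summarized against
somatic calls by group mean AF/depth and a one-sided Mann–Whitney test
(artifacts are expected at lower AF).

## Substitution spectra and recurrence

SNVs are collapsed to the six pyrimidine-strand classes (C>A, C>G, C>T, T>A,
T>C, T>G); purine references are reverse-complemented. Spectra are counts and
fractions per sample or patient — no trinucleotide context and no signature
decomposition, since six-class fractions are what this analysis interprets
(C>T dominance). Recurrence tables count a gene once per sample (or patient)
over the nonsynonymous classes only (frameshift/non-frameshift indel,
stop-gain/stop-loss, splicing, nonsynonymous SNV), sorted by count with the
gene symbol as tie-break, displayed as `k/N` with the percentage rounded to
the nearest integer. Functional classes are inputs: annotation is out of
scope.

## CCF estimation

For a mutation with multiplicity `m` (mutant copies per carrying cell) at a
locus of tumor copy number `C_t`, in a sample of purity `rho` and normal copy
number `C_n` (default 2), the expected variant allele fraction is

    E[VAF] = rho * m * CCF / (rho * C_t + (1 - rho) * C_n).

Multiplicity is fixed before estimation at
`m_hat = clamp(round(VAF * (rho*C_t + (1-rho)*C_n) / rho), 1, major_cn)`,
then the binomial likelihood `Binom(var | depth, E[VAF](c))` is maximized
over a CCF grid on [0, 1] with step 0.001 (ties toward the smaller CCF; the
estimate is capped at 1 because a CCF is a proportion). The 95% interval is
read off the normalized likelihood over the grid, widened if necessary to
contain the maximizer. This is a deterministic estimator of the same quantity
a Dirichlet-process sampler with Beta-Binomial emission targets. The
emission is binomial by default; a Beta-Binomial with configurable
concentration (`precision`) is available for overdispersed counts, off by
default because the emulated data are binomial. There is no joint
multi-sample model — the cost is quantified by the truth-recovery tests
(median absolute error < 0.05 at 170× and purity 0.8).

Known limitation: per-site multiplicity estimation assumes CCF ≈ 1 when
inverting the VAF relation, so at a CNA locus a subclonal mutation with
`m = 2` is indistinguishable from a clonal one with `m = 1` (e.g. m=2 at
CCF 0.6 maps to an apparent CCF of 1). Such loci surface as stray
high-CCF points; they are the reason the end-to-end recovery scenario below
uses copy-neutral loci, while the pipeline's recovery metrics retain CNA loci
and absorb the cost.

## Subclone clustering

Mutations are clustered on their CCF vectors across samples. At exome depth
the single-stage approach (one linkage cut) is not workable: with ~170×
coverage the per-sample CCF sampling noise is σ ≈ 0.08–0.09, and measurement
shows the final average-linkage merge height *inside* one true cluster
(median ≈ 0.24, p95 ≈ 0.31 for 40–120 members in two samples) overlaps the
merge height *between* subclones separated by ≈ 0.36 (p1 ≈ 0.31). Any fixed
cut therefore either shatters real clusters or fuses distinct ones.

The procedure is therefore staged, with every parameter in config:

1. **Fine cut** — average-linkage, Euclidean distance, cut at 0.15 CCF units.
2. **Center merge** — groups whose per-sample median centers are within
   `merge_threshold = 0.25` (≈ 3σ) are fused iteratively, closest pair
   first. Fragments of one subclone have centers within ~2σ of each other;
   subclones closer than 3σ in CCF space are below the method's resolution
   at this depth and deliberately report as one cluster.
3. **Satellite absorption** — a minor group (< 15% of the largest cluster)
   whose center lies within `absorb_threshold = 0.35` (≈ 4σ) of a larger
   cluster is folded into it. Extreme-tail points of a large cluster can
   survive stage 2 as a small satellite 3–4σ out; a genuinely distinct
   subclone this close to a major one is unresolvable anyway, while
   genuinely small subclones of the kind the analysis highlights
   (sample-private, CCF high in one sample and ~0 in the other) are far from
   every major cluster and untouched.

Clusters with fewer than 3 members are outliers: they remain in the output
but are excluded from flags, architecture enumeration, and cluster CCFs. A
cluster's CCF per sample is the median of its members' estimates (robust to
the stray points described above). Two flags follow: **ith** when the cluster
CCF is < 0.1 in some sample and > 0.5 in another (a quantification of
"very low in one sample, high in the other"), and **driver_candidate** when
the cluster CCF is strictly > 0.7 in every sample.

## Subclonal architectures

Two subclones are *linearly* related when one descends from the other (the
smaller-CCF clone arose inside cells carrying the larger) and *branching*
when they occupy disjoint cell populations. A rooted clone tree must satisfy,
in every sample and within tolerance ε (default 0.05, matching CCF noise at
this depth): each child's CCF ≤ its parent's (dominance), and each node's
children sum to ≤ the node's CCF (a population cannot be over-partitioned).
`enumerate_architectures` returns *every* rooted labeled tree over the
clusters meeting both constraints, by recursive parent assignment with early
pruning, verified in tests against exhaustive search over all labeled rooted
trees. The root is the cluster that dominates all others within ε (largest
total CCF breaks ties, then index order); if none dominates, a virtual root
with CCF 1 everywhere is inserted and reported. Enumeration is exponential
and capped at 10 clusters by default; ε-monotonicity (a tree valid at ε stays
valid at larger ε) holds whenever the root identity is stable, which a
truncal cluster guarantees. Trees are serialized as canonical parent maps and
topology-only Newick.

## Two-sample phylogeny

A mutation is present in a sample when its CCF exceeds 0.05 — the same floor
as the somatic AF filter, for consistency. Present-in-both mutations form the
trunk, present-in-one the two private branches, absent-in-both are excluded
but counted. The tree is root —trunk→ node →(leaf A, leaf B) with branch
lengths equal to mutation counts, written as Newick, e.g.
`(A:100,B:50):200;`.

## Forward simulator

The generator emulates the study conditions end to end: a random clone tree
(node 0 truncal; each node's parent has a smaller id), stick-breaking CCFs
(each node keeps a Beta-distributed fraction of its CCF and splits the rest
among children by a flat Dirichlet, so the lineage sum rule holds by
construction), optional zeroing of a non-root cluster in one sample
(probability 0.3) to create sample-private subclones — the zeroed subtree is
zeroed too, preserving the sum rule. Read counts are Poisson(170) depth with
binomial alt counts at the expected VAF above; multiplicity is drawn
uniformly from {1..major_cn} and recorded; 10% of loci carry a CNA state
drawn from {(2,1), (2,0), (2,2), (3,1)}, the rest are (1,1). Default purity
is 0.8 per sample (the study reports purity only qualitatively; 0.8 is
typical for macro-dissected FFPE tumor blocks and it is configurable
per sample). Substitutions follow a C>T-dominated six-class weight vector
(C>T 0.55), and each mutation receives a synthetic gene symbol and an
SNV-consistent functional class so the recurrence stage runs end to end.
FFPE artifacts are injected in *both* tissue roles at rate 0.05 per true
mutation with allele fractions drawn uniformly from (0.05, 0.1] (alt count =
round(AF·depth), keeping the realized AF in range) and are C>T with
probability 0.9, mimicking cytosine deamination. All randomness flows from
the config seed; identical configs reproduce byte-identical outputs.

What the simulator does **not** model: read-level errors and mapping
artifacts, tumor-in-normal contamination, germline variation (normal-role
counts are zero except artifacts), CNA segment structure along the genome
(copy states are per-locus), subclonal copy number, and overdispersed
(Beta-Binomial) counts. Passing recovery tests therefore demonstrate
correctness of the inference chain under binomial sampling noise at the
study's depth — not robustness to alignment artifacts or copy-number
misspecification in real data.

## Test and scenario sizes

Recovery tests run at the study's depth (170×) with problem sizes chosen so
each check is informative yet the suite completes in well under a minute of
CPU per module: 1,000 records for filter-oracle equivalence, 1,000 mutations
with 5% artifacts for swap QC, ~200 mutations for CCF recovery, 50 seeds for
clustering recovery, 100 random instances (k ≤ 5) for the architecture
oracle. The end-to-end scenario (truncal clone at CCF (1,1), shared subclone
at (0.75, 0.72), sample-private subclone at (0.6, 0)) uses 200 mutations per
cluster and purity 0.85: distinguishing a cluster median of 0.72 from the
strict 0.7 driver threshold requires the median's sampling sd
(≈ 1.25σ/√n ≈ 0.0077 at n = 200) to be well below the 0.02 margin, and the
corresponding patient in the emulated study had the highest sample quality.

## Known limitations

- Per-mutation, per-sample CCF estimation is independent; no joint
  multi-sample or multi-mutation model (no Dirichlet process, no MCMC).
- Multiplicity/CCF confounding at CNA loci, as described above.
- Subclones closer than ~0.25 in CCF space (at 170×) report as one cluster.
- Architecture enumeration reports all consistent trees without ranking;
  with many clusters of similar CCF the set can be large.
- The phylogeny covers exactly two tumor samples per patient, mirroring the
  study design it emulates.
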