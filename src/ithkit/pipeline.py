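"""End-to-end driver: simulate (optionally) then filter, spectra, recurrence,
CCF/cluster fit, architectures and phylogeny, with every table written as
tab-separated text and a JSON manifest tying the run together.

All randomness flows from the single configured seed; re-running with the
same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filters as _filters
from . import recurrence as _recur
from . import spectra as _spectra
from .model import SubcloneModel
from .simulate import SimConfig, simulate_patient
from .subclones import cluster_ccf_frame

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("ithkit.pipeline")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; see ``PipelineConfig.from_yaml``."""

    seed: int = 0
    simulation: dict = field(default_factory=dict)
    matched_normal: bool = True
    swap_use_matched_normal: bool = False
    cut_height: float = 0.15
    merge_threshold: float = 0.25
    min_cluster_size: int = 3
    grid_step: float = 0.001
    ith_low: float = 0.1
    ith_high: float = 0.5
    driver_threshold: float = 0.7
    epsilon: float = 0.05
    max_clusters: int = 10
    presence_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def sim_config(self) -> SimConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        if "purity_per_sample" in sim and isinstance(sim["purity_per_sample"], list):
            sim["purity_per_sample"] = tuple(sim["purity_per_sample"])
        if "artifact_af_range" in sim:
            sim["artifact_af_range"] = tuple(sim["artifact_af_range"])
        return SimConfig(**sim)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> str:
    df.to_csv(path, sep="\t", index=index)
    return path.name


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a simulated patient and write the report bundle.

    Returns the manifest (also written as ``manifest.json``): stage -> list of
    output files, plus the echoed parameters and recovery metrics against the
    simulation truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": {}, "skipped": []}
    logger.info("pipeline start: seed=%d out_dir=%s", config.seed, out)

    # -- stage 0: simulation ---------------------------------------------
    sim_cfg = config.sim_config()
    data = simulate_patient(sim_cfg)
    truth = data.truth
    files = [
        _write(data.observations, out / "observations.tsv", index=False),
        _write(data.variants, out / "variants.tsv"),
        _write(truth.ccf_matrix.rename_axis("cluster_id"), out / "truth_ccf_matrix.tsv"),
        _write(
            pd.Series(truth.mutation_assignments, name="cluster_id")
            .rename_axis("mutation_id")
            .to_frame(),
            out / "truth_assignments.tsv",
        ),
    ]
    config.to_yaml(out / "config.yaml")
    files.append("config.yaml")
    manifest["stages"]["simulate"] = files
    logger.info("simulated %d mutations x %d samples", len(truth.mutation_assignments), sim_cfg.n_samples)

    # -- stage 1: filtering + swap QC ------------------------------------
    tumor = data.tumor_variants
    normal = data.normal_variants
    report = _filters.apply_somatic_filters(tumor, has_matched_normal=config.matched_normal)
    somatic = tumor.loc[report.surviving_ids]
    (out / "filter_summary.txt").write_text(report.summary() + "\n")
    files = [_write(somatic, out / "somatic_calls.tsv"), "filter_summary.txt"]
    if config.matched_normal and len(normal):
        swap = _filters.swap_artifact_scan(
            tumor, normal, use_matched_normal=config.swap_use_matched_normal
        )
        artifacts = normal.loc[swap.artifact_ids]
        files.append(_write(artifacts, out / "artifactual_calls.tsv"))
        if len(artifacts) and len(somatic):
            profile = _filters.compare_artifact_profiles(artifacts, somatic)
            (out / "artifact_profile.json").write_text(json.dumps(profile, indent=2) + "\n")
            files.append("artifact_profile.json")
    else:
        manifest["skipped"].append("swap_qc: no matched normal sample")
        logger.info("swap QC skipped: no matched normal sample")
    manifest["stages"]["filter"] = files

    # -- stage 2: spectra -------------------------------------------------
    per_mutation = somatic.drop_duplicates("mutation_id")
    spectrum = _spectra.compute_spectrum(somatic, group_by="sample_id")
    spectrum_all = _spectra.compute_spectrum(per_mutation.assign(patient="patient"), group_by="patient")
    manifest["stages"]["spectra"] = [
        _write(spectrum, out / "spectrum_by_sample.tsv"),
        _write(spectrum_all, out / "spectrum_patient.tsv"),
    ]

    # -- stage 3: recurrence ----------------------------------------------
    rec_tab = _recur.recurrence_table(somatic, level="sample")
    heat = _recur.heatmap_matrix(somatic)
    manifest["stages"]["recurrence"] = [
        _write(rec_tab, out / "recurrence_by_sample.tsv", index=False),
        _write(heat, out / "recurrence_heatmap.tsv"),
    ]

    # -- stages 4+5: CCF estimation and subclone clustering ---------------
    surviving_mutations = set(somatic["mutation_id"])
    observations = data.observations[
        data.observations["mutation_id"].isin(surviving_mutations)
    ]
    purity = dict(zip(sim_cfg.sample_ids(), sim_cfg.purities()))
    model = SubcloneModel(observations, purity=purity)
    res = model.fit(
        grid_step=config.grid_step,
        cut_height=config.cut_height,
        merge_threshold=config.merge_threshold,
        min_cluster_size=config.min_cluster_size,
        ith_low=config.ith_low,
        ith_high=config.ith_high,
        driver_threshold=config.driver_threshold,
    )
    manifest["stages"]["ccf"] = [
        _write(res.ccf_estimates, out / "ccf_estimates.tsv", index=False),
        _write(res.ccf_matrix, out / "ccf_matrix.tsv"),
    ]
    scatter = res.scatter_table() if len(res.samples) == 2 else None
    files = [
        _write(res.cluster_table(), out / "clusters.tsv"),
        _write(res.assignments().rename_axis("mutation_id").to_frame(), out / "assignments.tsv"),
    ]
    if scatter is not None:
        files.append(_write(scatter, out / "scatter.tsv"))
    violin = res.ccf_estimates.merge(
        res.assignments().rename("cluster_id"), left_on="mutation_id", right_index=True
    )[["cluster_id", "sample_id", "mutation_id", "ccf_hat"]]
    files.append(_write(violin.sort_values(["cluster_id", "sample_id", "mutation_id"]),
                        out / "violin_data.tsv", index=False))
    (out / "subclone_summary.txt").write_text(res.summary() + "\n")
    files.append("subclone_summary.txt")
    manifest["stages"]["cluster"] = files

    # -- stage 6: architectures -------------------------------------------
    frame = cluster_ccf_frame(res.clusters)
    if len(frame) and len(frame) <= config.max_clusters:
        archs = res.architectures(epsilon=config.epsilon, max_clusters=config.max_clusters)
        edge_rows = [
            {"architecture": i, "child": c, "parent": p}
            for i, a in enumerate(archs)
            for c, p in a.parent
        ]
        arch_files = [
            _write(pd.DataFrame(edge_rows), out / "architectures_edges.tsv", index=False)
        ]
        (out / "architectures.nwk").write_text(
            "".join(a.to_newick() + "\n" for a in archs)
        )
        arch_files.append("architectures.nwk")
        (out / "architecture_count.txt").write_text(f"{len(archs)}\n")
        arch_files.append("architecture_count.txt")
        manifest["stages"]["architecture"] = arch_files
    else:
        manifest["skipped"].append("architecture: cluster count outside enumeration cap")

    # -- stage 7: phylogeny -----------------------------------------------
    if len(res.samples) == 2:
        part = res.phylo_partition(presence_threshold=config.presence_threshold)
        tree = res.phylogeny(presence_threshold=config.presence_threshold)
        (out / "phylogeny.nwk").write_text(tree.to_newick() + "\n")
        genes = somatic.drop_duplicates("mutation_id").set_index("mutation_id")["gene"]
        branches = tree.branch_table()
        branches["example_genes"] = [
            ",".join(sorted(set(genes.reindex(ids).dropna()))[:5])
            for ids in (part.trunk, part.private_a, part.private_b)
        ]
        manifest["stages"]["phylogeny"] = [
            "phylogeny.nwk",
            _write(branches, out / "phylogeny_branches.tsv", index=False),
        ]
    else:
        manifest["skipped"].append("phylogeny: needs exactly two tumor samples")

    # -- truth recovery metrics -------------------------------------------
    manifest["recovery"] = _recovery_metrics(data, res)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    logger.info("pipeline done: %d stages", len(manifest["stages"]))
    return manifest


def _recovery_metrics(data, res) -> dict:
    """Truth-vs-estimate metrics for a simulated run."""
    truth = data.truth
    est = res.ccf_estimates
    true_ccf = [
        float(truth.ccf_matrix.at[truth.mutation_assignments[m], s])
        for m, s in zip(est["mutation_id"], est["sample_id"])
    ]
    err = np.abs(est["ccf_hat"].to_numpy() - np.array(true_ccf))
    assign = res.assignments()
    shared = [m for m in assign.index if m in truth.mutation_assignments]
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(
        [truth.mutation_assignments[m] for m in shared], [assign[m] for m in shared]
    )
    return {
        "ccf_median_abs_error": float(np.median(err)),
        "clustering_ari": float(ari),
        "n_true_clusters": int(truth.ccf_matrix.shape[0]),
        "n_recovered_clusters": int(sum(not c.is_outlier for c in res.clusters)),
    }
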