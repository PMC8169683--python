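"""Somatic and germline variant filter cascades plus the tumor/normal swap QC.

The cascades apply fixed per-record thresholds, with comparison directions as
commonly printed for exome calling pipelines:

somatic (tumor-role records)
    depth > 25; mutant AF > 0.05; matched-normal AF < 0.01 when a matched
    normal exists; not listed in 1000 Genomes or ESP.  All strict.

germline (normal-role records)
    depth >= 50; genotype quality >= 30; 0.3 <= AF <= 0.7; not multi-allelic;
    VQSR tranche score <= 97.00; not in a segmental duplication.  All
    boundaries inclusive.

The swap QC re-runs the somatic cascade with tumor and normal roles exchanged:
calls that pass when the FFPE normal is treated as the tumor are declared
artifactual.  By default the cross-sample matched-normal criterion is not
applied in swap mode — an FFPE artifact typically appears at low AF in *both*
blocks, and conditioning on the tumor's AF would mask exactly those shared
artifacts (set ``use_matched_normal=True`` for the fully symmetric variant).

Records travel as pandas DataFrames; the index is the record identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = [
    "FilterReport",
    "SOMATIC_THRESHOLDS",
    "GERMLINE_THRESHOLDS",
    "apply_somatic_filters",
    "apply_germline_filters",
    "swap_artifact_scan",
    "compare_artifact_profiles",
]

SOMATIC_THRESHOLDS = {"min_depth": 25, "min_af": 0.05, "max_normal_af": 0.01}
GERMLINE_THRESHOLDS = {
    "min_depth": 50,
    "min_gq": 30,
    "af_low": 0.3,
    "af_high": 0.7,
    "max_vqsr": 97.00,
}


@dataclass
class FilterReport:
    """Outcome of one cascade over a record table."""

    mode: str
    n_input: int
    surviving_ids: list = field(default_factory=list)
    criterion_failures: dict[str, int] = field(default_factory=dict)
    artifact_ids: list | None = None

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_ids)

    @property
    def n_failed(self) -> int:
        return self.n_input - self.n_surviving

    def summary(self) -> str:
        lines = [
            f"{self.mode} filter: {self.n_surviving}/{self.n_input} records pass",
            "failures per criterion (a record may fail several):",
        ]
        for name, count in self.criterion_failures.items():
            lines.append(f"  {name}: {count}")
        if self.artifact_ids is not None:
            lines.append(f"artifactual calls: {len(self.artifact_ids)}")
        return "\n".join(lines)


def _af_column(records: pd.DataFrame) -> pd.Series:
    """AF as given, or alt_count/depth where absent; depth 0 yields AF 0."""
    depth = records["depth"].astype(float)
    computed = records["alt_count"].where(depth > 0, 0).div(depth.where(depth > 0, 1))
    if "af" in records.columns:
        return records["af"].astype(float).fillna(computed)
    return computed


def _report(records: pd.DataFrame, mode: str, passes: dict[str, pd.Series]) -> FilterReport:
    surviving = pd.Series(True, index=records.index)
    failures = {}
    for name, mask in passes.items():
        mask = mask.fillna(False).astype(bool)
        failures[name] = int((~mask).sum())
        surviving &= mask
    return FilterReport(
        mode=mode,
        n_input=len(records),
        surviving_ids=list(records.index[surviving]),
        criterion_failures=failures,
    )


def apply_somatic_filters(records: pd.DataFrame, has_matched_normal: bool) -> FilterReport:
    """Apply the four somatic criteria to tumor-role records.

    Raises
    ------
    KeyError
        If ``has_matched_normal`` but any record lacks ``matched_normal_af``.
    """
    af = _af_column(records)
    passes = {
        "depth_gt_25": records["depth"] > SOMATIC_THRESHOLDS["min_depth"],
        "af_gt_0.05": af > SOMATIC_THRESHOLDS["min_af"],
    }
    if has_matched_normal:
        if "matched_normal_af" not in records.columns or records["matched_normal_af"].isna().any():
            raise KeyError("matched_normal_af required for every record when a matched normal exists")
        passes["normal_af_lt_0.01"] = (
            records["matched_normal_af"] < SOMATIC_THRESHOLDS["max_normal_af"]
        )
    passes["not_in_1000g"] = ~records["in_1000g"].astype(bool)
    passes["not_in_esp"] = ~records["in_esp"].astype(bool)
    return _report(records, "somatic", passes)


def apply_germline_filters(records: pd.DataFrame) -> FilterReport:
    """Apply the six germline criteria to normal-role records.

    Missing GQ or VQSR values fail their criterion rather than erroring.
    """
    af = _af_column(records)
    t = GERMLINE_THRESHOLDS
    passes = {
        "depth_ge_50": records["depth"] >= t["min_depth"],
        "gq_ge_30": records["gq"] >= t["min_gq"],
        "af_in_0.3_0.7": (af >= t["af_low"]) & (af <= t["af_high"]),
        "not_multiallelic": ~records["is_multiallelic"].astype(bool),
        "vqsr_le_97": records["vqsr"] <= t["max_vqsr"],
        "not_in_segdup": ~records["in_segdup"].astype(bool),
    }
    return _report(records, "germline", passes)


def swap_artifact_scan(
    tumor_records: pd.DataFrame,
    normal_records: pd.DataFrame,
    use_matched_normal: bool = False,
) -> FilterReport:
    """Detect FFPE artifacts by running the somatic cascade with roles swapped.

    Normal-role records are treated as the tumor; survivors are artifactual.
    With ``use_matched_normal=True`` the original tumor's AF (maximum across
    tumor samples at the same variant) additionally has to be < 0.01, i.e. the
    cascade is applied fully symmetrically.

    Raises
    ------
    ValueError
        If either role is absent (patients without matched normals have no
        swap QC).
    """
    if tumor_records is None or normal_records is None or len(normal_records) == 0:
        raise ValueError("swap QC needs both tumor and normal records for the patient")

    swapped = normal_records.copy()
    if use_matched_normal:
        key_cols = ["chrom", "pos", "ref", "alt"]
        tumor_af = tumor_records.assign(af=_af_column(tumor_records))
        max_af = tumor_af.groupby(key_cols)["af"].max()
        keys = pd.MultiIndex.from_frame(swapped[key_cols])
        swapped["matched_normal_af"] = max_af.reindex(keys).fillna(0.0).to_numpy()
        report = apply_somatic_filters(swapped, has_matched_normal=True)
    else:
        report = apply_somatic_filters(swapped, has_matched_normal=False)
    report.mode = "swap"
    report.artifact_ids = report.surviving_ids
    report.surviving_ids = []
    return report


def compare_artifact_profiles(
    artifacts: pd.DataFrame, somatic: pd.DataFrame
) -> dict[str, float | bool]:
    """Contrast artifactual and somatic calls on AF and depth.

    Returns group means plus a one-sided Mann-Whitney comparison of AFs
    (alternative: artifact AF < somatic AF) and a flag for whether the
    artifact mean AF is strictly below the somatic mean AF.

    Raises
    ------
    ValueError
        If either table is empty.
    """
    if len(artifacts) == 0 or len(somatic) == 0:
        raise ValueError("both artifact and somatic tables must be non-empty")
    art_af = _af_column(artifacts)
    som_af = _af_column(somatic)
    pvalue = float(stats.mannwhitneyu(art_af, som_af, alternative="less").pvalue)
    return {
        "artifact_mean_af": float(art_af.mean()),
        "somatic_mean_af": float(som_af.mean()),
        "artifact_mean_depth": float(artifacts["depth"].mean()),
        "somatic_mean_depth": float(somatic["depth"].mean()),
        "artifact_af_lower": bool(art_af.mean() < som_af.mean()),
        "mannwhitney_p": pvalue,
    }
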