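"""Model/results interface to the subclonal-reconstruction core.

:class:`SubcloneModel` is built from a PyClone-style observation table plus
sample purities; :meth:`SubcloneModel.fit` estimates per-mutation CCFs by
binomial grid maximum likelihood, clusters them into subclones, applies the
outlier rule and the ITH / driver-candidate flags, and returns a
:class:`SubcloneResults` carrying the estimates, their 95% intervals and the
cluster table.  Architectures and the two-sample phylogeny hang off the
results object, as does plotting.

Example
-------
>>> model = SubcloneModel(observations, purity=0.8)
>>> res = model.fit()
>>> print(res.summary())
>>> trees = res.architectures()
>>> newick = res.phylogeny("T1", "T2").to_newick()
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import architecture as _arch
from . import ccf as _ccf
from . import phylogeny as _phylo
from . import subclones as _sub

__all__ = ["SubcloneModel", "SubcloneResults"]


class SubcloneModel:
    """Subclonal reconstruction model for one patient.

    Parameters
    ----------
    observations
        Table with columns ``mutation_id sample_id ref_counts var_counts
        major_cn minor_cn`` (optionally ``normal_cn``), one row per mutation
        per tumor sample.
    purity
        Tumor cell fraction: a scalar applied to all samples or a mapping
        sample_id -> purity.
    normal_cn
        Copy number of the locus in normal cells (default 2).
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        purity: float | Mapping[str, float],
        normal_cn: int = 2,
    ) -> None:
        required = {"mutation_id", "sample_id", "ref_counts", "var_counts", "major_cn", "minor_cn"}
        if missing := required - set(observations.columns):
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        self.observations = observations.reset_index(drop=True)
        self.purity = purity
        self.normal_cn = normal_cn

    @classmethod
    def from_table(
        cls, path, purity: float | Mapping[str, float], normal_cn: int = 2
    ) -> "SubcloneModel":
        """Build the model from a tab-separated observation file."""
        from .io import read_observation_table

        return cls(read_observation_table(path), purity, normal_cn)

    def fit(
        self,
        grid_step: float = _ccf.DEFAULT_GRID_STEP,
        cut_height: float = _sub.DEFAULT_CUT_HEIGHT,
        merge_threshold: float = _sub.DEFAULT_MERGE_THRESHOLD,
        min_cluster_size: int = _sub.DEFAULT_MIN_CLUSTER_SIZE,
        ith_low: float = 0.1,
        ith_high: float = 0.5,
        driver_threshold: float = 0.7,
    ) -> "SubcloneResults":
        """Estimate CCFs, cluster subclones and flag them."""
        estimates = _ccf.estimate_ccf_table(
            self.observations, self.purity, normal_cn_default=self.normal_cn, grid_step=grid_step
        )
        matrix = _ccf.ccf_matrix(estimates)
        clusters = _sub.cluster_mutations(
            matrix,
            cut_height=cut_height,
            merge_threshold=merge_threshold,
            min_cluster_size=min_cluster_size,
        )
        _sub.flag_ith_subclones(clusters, low=ith_low, high=ith_high)
        _sub.flag_driver_subclones(clusters, threshold=driver_threshold)
        params = dict(
            grid_step=grid_step,
            cut_height=cut_height,
            merge_threshold=merge_threshold,
            min_cluster_size=min_cluster_size,
            ith_low=ith_low,
            ith_high=ith_high,
            driver_threshold=driver_threshold,
        )
        return SubcloneResults(self, estimates, matrix, clusters, params)


class SubcloneResults:
    """Fitted subclonal structure: estimates, clusters, flags, trees."""

    def __init__(self, model, ccf_estimates, ccf_matrix, clusters, params) -> None:
        self.model = model
        self.ccf_estimates: pd.DataFrame = ccf_estimates
        self.ccf_matrix: pd.DataFrame = ccf_matrix
        self.clusters: list[_sub.SubcloneCluster] = clusters
        self.params: dict = params

    # -- tables -----------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.ccf_matrix.columns)

    def cluster_table(self) -> pd.DataFrame:
        """One row per cluster: size, per-sample CCF, outlier/ITH/driver flags."""
        rows = []
        for c in self.clusters:
            row = {"cluster_id": c.cluster_id, "n": c.n}
            for s, v in c.ccf.items():
                row[f"ccf_{s}"] = float(v)
            row.update(
                is_outlier=c.is_outlier, ith=c.ith, driver_candidate=c.driver_candidate
            )
            rows.append(row)
        return pd.DataFrame(rows).set_index("cluster_id")

    def assignments(self) -> pd.Series:
        return _sub.assignments_series(self.clusters)

    def scatter_table(self, sample_a: str | None = None, sample_b: str | None = None) -> pd.DataFrame:
        a, b = self._sample_pair(sample_a, sample_b)
        return _sub.scatter_table(self.ccf_matrix, self.clusters, a, b)

    # -- downstream structures -------------------------------------------

    def architectures(
        self, epsilon: float = 0.05, max_clusters: int = 10
    ) -> list[_arch.Architecture]:
        """All clone trees over the non-outlier clusters consistent with the
        dominance and lineage-sum constraints at tolerance ``epsilon``."""
        frame = _sub.cluster_ccf_frame(self.clusters)
        config = _arch.ArchitectureConfig(epsilon=epsilon, max_clusters=max_clusters)
        return _arch.enumerate_architectures(frame, config)

    def phylogeny(
        self,
        sample_a: str | None = None,
        sample_b: str | None = None,
        presence_threshold: float = _phylo.DEFAULT_PRESENCE_THRESHOLD,
    ) -> _phylo.PhyloTree:
        a, b = self._sample_pair(sample_a, sample_b)
        part = _phylo.partition_mutations(self.ccf_matrix, a, b, presence_threshold)
        return _phylo.build_tree(part)

    def phylo_partition(
        self,
        sample_a: str | None = None,
        sample_b: str | None = None,
        presence_threshold: float = _phylo.DEFAULT_PRESENCE_THRESHOLD,
    ) -> _phylo.PhyloPartition:
        a, b = self._sample_pair(sample_a, sample_b)
        return _phylo.partition_mutations(self.ccf_matrix, a, b, presence_threshold)

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        """Human-readable account of the fitted subclonal structure."""
        tab = self.cluster_table()
        n_out = int(tab["is_outlier"].sum())
        lines = [
            "Subclonal reconstruction",
            "=" * 60,
            f"mutations: {self.ccf_matrix.shape[0]}   samples: {', '.join(self.samples)}",
            f"clusters: {len(tab)} ({len(tab) - n_out} non-outlier, {n_out} outlier)",
            f"cut height: {self.params['cut_height']}   min cluster size: "
            f"{self.params['min_cluster_size']}",
            "",
            tab.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        ith = tab.index[tab["ith"]].tolist()
        drv = tab.index[tab["driver_candidate"]].tolist()
        lines.append("")
        lines.append(f"ITH subclones (sample-private): {ith if ith else 'none'}")
        lines.append(f"driver-candidate subclones (CCF > {self.params['driver_threshold']} "
                     f"in all samples): {drv if drv else 'none'}")
        return "\n".join(lines)

    def plot_ccf(self, sample_a: str | None = None, sample_b: str | None = None, ax=None):
        """Two-sample CCF scatter colored by cluster (outliers light grey)."""
        from .plotting import plot_ccf_scatter

        a, b = self._sample_pair(sample_a, sample_b)
        return plot_ccf_scatter(self.scatter_table(a, b), a, b, ax=ax)

    def _sample_pair(self, sample_a, sample_b) -> tuple[str, str]:
        samples = self.samples
        if sample_a is None and sample_b is None:
            if len(samples) != 2:
                raise ValueError("specify sample_a and sample_b when not exactly 2 samples")
            return samples[0], samples[1]
        if sample_a is None or sample_b is None:
            raise ValueError("specify both samples or neither")
        return sample_a, sample_b
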