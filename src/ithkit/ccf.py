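"""Cancer-cell-fraction (CCF) estimation from allele counts.

The CCF of a mutation in a sample is the proportion of tumor cells that carry
it.  For a mutation at multiplicity ``m`` (mutant-allele copies per carrying
cell) in a region of tumor copy number ``C_t``, in a sample of purity ``rho``
with normal copy number ``C_n``, the expected variant allele fraction is

    E[VAF] = rho * m * CCF / (rho * C_t + (1 - rho) * C_n)

Each observation is inverted independently by maximizing the binomial
likelihood Binom(var_counts | depth, E[VAF](ccf)) over a regular CCF grid on
[0, 1].  Multiplicity is fixed beforehand at a moment-style estimate clamped to
{1, ..., major_cn}; the 95% interval is read off the normalized likelihood
over the grid.  This is a deterministic point estimator of the same quantity
that Bayesian samplers such as PyClone target with a full posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CcfEstimate",
    "expected_vaf",
    "estimate_multiplicity",
    "estimate_ccf",
    "estimate_ccf_table",
    "ccf_matrix",
]

DEFAULT_GRID_STEP = 0.001


@dataclass(frozen=True)
class CcfEstimate:
    """Point estimate and 95% likelihood interval for one observation."""

    ccf_hat: float
    ci_low: float
    ci_high: float
    multiplicity_hat: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.ccf_hat <= self.ci_high <= 1.0:
            raise ValueError(
                f"inconsistent estimate: {self.ci_low} <= {self.ccf_hat} <= {self.ci_high}"
            )


def expected_vaf(
    ccf: float, purity: float, multiplicity: int, total_cn: int, normal_cn: int = 2
) -> float:
    """Expected variant allele fraction under the purity/copy-number model."""
    if total_cn < multiplicity:
        raise ValueError(f"total_cn={total_cn} < multiplicity={multiplicity}")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    return (purity * multiplicity * ccf) / (purity * total_cn + (1.0 - purity) * normal_cn)


def estimate_multiplicity(
    var_counts: int,
    ref_counts: int,
    purity: float,
    major_cn: int,
    minor_cn: int,
    normal_cn: int = 2,
) -> int:
    """Moment estimate of mutant-allele multiplicity, clamped to [1, major_cn].

    Inverts the expected-VAF relation at CCF = 1 and rounds:
    ``m_hat = round(VAF * (rho*C_t + (1-rho)*C_n) / rho)``.
    """
    depth = var_counts + ref_counts
    if depth <= 0:
        raise ValueError("zero-depth observation")
    vaf = var_counts / depth
    total_cn = major_cn + minor_cn
    m = round(vaf * (purity * total_cn + (1.0 - purity) * normal_cn) / purity)
    return int(min(max(m, 1), max(major_cn, 1)))


def _grid_loglik(
    var: int, depth: int, vaf_grid: np.ndarray, precision: float | None = None
) -> np.ndarray:
    # log-likelihood up to a constant; -inf where the data contradict a
    # degenerate expected VAF of exactly 0 or 1.  With a finite precision s
    # the emission is Beta-Binomial with mean v and concentration s
    # (overdispersion knob; None = pure binomial).
    if precision is not None:
        from scipy import stats

        inner = np.clip(vaf_grid, 1e-12, 1.0 - 1e-12)
        ll = stats.betabinom.logpmf(var, depth, inner * precision, (1.0 - inner) * precision)
        ll[(vaf_grid == 0.0) & (var > 0)] = -np.inf
        ll[(vaf_grid == 1.0) & (var < depth)] = -np.inf
        return ll
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = var * np.log(vaf_grid) + (depth - var) * np.log1p(-vaf_grid)
    if var == 0:
        ll[vaf_grid == 0.0] = 0.0
    if var == depth:
        ll[vaf_grid == 1.0] = 0.0
    return ll


def estimate_ccf(
    var_counts: int,
    ref_counts: int,
    purity: float,
    major_cn: int,
    minor_cn: int,
    normal_cn: int = 2,
    grid_step: float = DEFAULT_GRID_STEP,
    ci_level: float = 0.95,
    precision: float | None = None,
) -> CcfEstimate:
    """Grid maximum-likelihood CCF for one observation.

    The grid maximizer on [0, 1] (ties broken toward the smaller CCF) is the
    point estimate; the interval bounds are the ``(1-ci_level)/2`` and
    ``1-(1-ci_level)/2`` quantiles of the likelihood normalized over the grid,
    widened if needed to contain the maximizer.  ``precision`` switches the
    emission from binomial to Beta-Binomial with that concentration
    (overdispersed counts; larger means closer to binomial).

    Raises
    ------
    ValueError
        On a zero-depth observation or invalid copy state.
    """
    depth = var_counts + ref_counts
    if depth <= 0:
        raise ValueError("zero-depth observation")
    if minor_cn > major_cn or minor_cn < 0 or major_cn < 1:
        raise ValueError(f"invalid copy state major={major_cn} minor={minor_cn}")
    m_hat = estimate_multiplicity(var_counts, ref_counts, purity, major_cn, minor_cn, normal_cn)
    total_cn = major_cn + minor_cn
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid[-1] = 1.0
    vaf = (purity * m_hat * grid) / (purity * total_cn + (1.0 - purity) * normal_cn)
    ll = _grid_loglik(var_counts, depth, vaf, precision=precision)
    ccf_hat = float(grid[int(np.argmax(ll))])

    lik = np.exp(ll - ll.max())
    cdf = np.cumsum(lik)
    cdf /= cdf[-1]
    alpha = (1.0 - ci_level) / 2.0
    ci_low = float(grid[int(np.searchsorted(cdf, alpha))])
    ci_high = float(grid[int(np.searchsorted(cdf, 1.0 - alpha))])
    ci_low = min(ci_low, ccf_hat)
    ci_high = max(ci_high, ccf_hat)
    return CcfEstimate(ccf_hat, ci_low, ci_high, m_hat)


def estimate_ccf_table(
    observations: pd.DataFrame,
    purity: float | Mapping[str, float],
    normal_cn_default: int = 2,
    grid_step: float = DEFAULT_GRID_STEP,
    precision: float | None = None,
) -> pd.DataFrame:
    """Estimate CCFs for a PyClone-style observation table.

    Parameters
    ----------
    observations
        Columns ``mutation_id sample_id ref_counts var_counts major_cn
        minor_cn`` and optionally ``normal_cn``.
    purity
        Scalar purity for all samples or a mapping sample_id -> purity.

    Returns
    -------
    One row per observation with ``ccf_hat``, ``ci_low``, ``ci_high`` and
    ``multiplicity_hat`` appended.
    """
    rows = []
    for rec in observations.itertuples(index=False):
        rho = purity[rec.sample_id] if isinstance(purity, Mapping) else float(purity)
        n_cn = int(getattr(rec, "normal_cn", normal_cn_default))
        est = estimate_ccf(
            int(rec.var_counts),
            int(rec.ref_counts),
            rho,
            int(rec.major_cn),
            int(rec.minor_cn),
            normal_cn=n_cn,
            grid_step=grid_step,
            precision=precision,
        )
        rows.append((est.ccf_hat, est.ci_low, est.ci_high, est.multiplicity_hat))
    out = observations.copy()
    out[["ccf_hat", "ci_low", "ci_high", "multiplicity_hat"]] = pd.DataFrame(
        rows, index=observations.index
    )
    return out


def ccf_matrix(estimates: pd.DataFrame, value_col: str = "ccf_hat") -> pd.DataFrame:
    """Pivot an estimate table to a mutations x samples CCF matrix.

    Mutations absent from a sample get CCF 0 (no missing cells).
    """
    mat = estimates.pivot_table(
        index="mutation_id", columns="sample_id", values=value_col, aggfunc="first"
    )
    return mat.fillna(0.0)
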