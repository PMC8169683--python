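"""Six-class substitution spectra.

Single-nucleotide variants are collapsed onto the pyrimidine strand, giving the
six canonical substitution classes C>A, C>G, C>T, T>A, T>C, T>G.  Purine
reference bases (A, G) are reverse-complemented before classification, so e.g.
G>A counts as C>T.  FFPE-damaged and many breast-tumor exomes are dominated by
C>T transitions, which is the main signal these spectra are meant to surface.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SUBSTITUTION_CLASSES",
    "classify_substitution",
    "compute_spectrum",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = frozenset("CT")


def classify_substitution(ref: str, alt: str) -> str:
    """Return the pyrimidine-strand substitution class of a SNV.

    Parameters
    ----------
    ref, alt
        Single bases in {A, C, G, T}, with ``ref != alt``.

    Raises
    ------
    TypeError
        If either allele is not a single A/C/G/T base (indels and MNVs are
        excluded from spectra).
    ValueError
        If ``ref == alt``.
    """
    ref = str(ref).upper()
    alt = str(alt).upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise TypeError(f"not a SNV: ref={ref!r} alt={alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if ref not in _PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def compute_spectrum(
    mutations: pd.DataFrame,
    group_by: str = "sample_id",
    ref_col: str = "ref",
    alt_col: str = "alt",
) -> pd.DataFrame:
    """Per-group substitution spectra: counts, fractions and dominant class.

    Parameters
    ----------
    mutations
        One row per SNV with reference/alternate base columns and the grouping
        column (typically ``sample_id`` or ``patient_id``).
    group_by
        Column to aggregate over.

    Returns
    -------
    DataFrame indexed by group with one count column per class, matching
    ``<class>_frac`` fraction columns, ``total``, ``dominant_class`` and an
    ``undefined_fractions`` flag for empty groups (fractions are NaN there).
    """
    if mutations.empty:
        cols = list(SUBSTITUTION_CLASSES)
        out = pd.DataFrame(columns=cols)
        out.index.name = group_by
        out["total"] = pd.Series(dtype=int)
        return out

    classes = [
        classify_substitution(r, a)
        for r, a in zip(mutations[ref_col], mutations[alt_col])
    ]
    groups = mutations[group_by]
    tab = (
        pd.crosstab(groups, pd.Categorical(classes, categories=SUBSTITUTION_CLASSES))
        .reindex(columns=list(SUBSTITUTION_CLASSES), fill_value=0)
    )
    if isinstance(groups.dtype, pd.CategoricalDtype):
        # keep declared-but-unobserved groups as zero-count rows
        tab = tab.reindex(groups.cat.categories, fill_value=0)
    tab.index.name = group_by
    total = tab.sum(axis=1)
    fracs = tab.div(total.where(total > 0), axis=0)
    for cls in SUBSTITUTION_CLASSES:
        tab[f"{cls}_frac"] = fracs[cls]
    tab["total"] = total
    tab["dominant_class"] = None
    nonempty = total > 0
    if nonempty.any():
        tab.loc[nonempty, "dominant_class"] = fracs.loc[nonempty].idxmax(axis=1)
    tab["undefined_fractions"] = total == 0
    return tab
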