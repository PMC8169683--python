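"""Readers and writers for the formats the pipeline touches.

Variant records travel as a minimal VCF v4.2 subset (CHROM/POS/REF/ALT, INFO
``VQSR``/``KG1000``/``ESP``/``SEGDUP``, per-sample ``AD``/``DP``/``GQ``) read
and written through pysam; everything tabular is tab-separated.  Copy-number
segments follow the TITAN convention of 1-based inclusive intervals; any BED
export would be 0-based half-open, and that conversion lives in exactly one
place (:func:`to_bed_interval`).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "read_vcf_minimal",
    "write_vcf_minimal",
    "read_observation_table",
    "write_observation_table",
    "read_segments",
    "assign_copy_number",
    "attach_matched_normal_af",
    "to_bed_interval",
]

OBSERVATION_COLUMNS = [
    "mutation_id",
    "ref_counts",
    "var_counts",
    "normal_cn",
    "minor_cn",
    "major_cn",
    "sample_id",
]

_VCF_HEADER_LINES = [
    ('INFO', 'VQSR', '1', 'Float', 'VQSR tranche score'),
    ('INFO', 'KG1000', '0', 'Flag', 'Listed in 1000 Genomes Project'),
    ('INFO', 'ESP', '0', 'Flag', 'Listed in Exome Sequencing Project'),
    ('INFO', 'SEGDUP', '0', 'Flag', 'Falls in a segmental duplication'),
    ('FORMAT', 'AD', 'R', 'Integer', 'Allelic depths (ref, alt)'),
    ('FORMAT', 'DP', '1', 'Integer', 'Read depth'),
    ('FORMAT', 'GQ', '1', 'Integer', 'Genotype quality'),
]


def read_vcf_minimal(
    path: str | Path, sample_roles: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Parse a minimal VCF into a long-format variant-record table.

    One output row per (site, sample); positions stay 1-based.  Multi-allelic
    rows are flagged, not split (only the first ALT is reported).

    Parameters
    ----------
    sample_roles
        Optional mapping sample name -> ``"tumor"``/``"normal"``; samples not
        listed default to tumor.

    Raises
    ------
    ValueError
        On a malformed row, with the 1-based data line number.
    """
    sample_roles = dict(sample_roles or {})
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        declared = set(vcf.header.info.keys())
        for lineno, rec in enumerate(vcf, start=1):
            try:
                alts = rec.alts or ()
                alt = alts[0] if alts else "."
                multi = len(alts) > 1
                vqsr = rec.info.get("VQSR", None) if "VQSR" in declared else None
                for sample in rec.samples:
                    fmt = rec.samples[sample]
                    ad = fmt.get("AD")
                    depth = fmt.get("DP")
                    alt_count = int(ad[1]) if ad is not None and len(ad) > 1 and ad[1] is not None else 0
                    if depth is None:
                        depth = int(sum(x for x in ad if x is not None)) if ad is not None else 0
                    gq = fmt.get("GQ")
                    rows.append(
                        dict(
                            record_id=f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}:{sample}",
                            chrom=rec.chrom,
                            pos=int(rec.pos),
                            ref=rec.ref,
                            alt=alt,
                            sample_id=sample,
                            role=sample_roles.get(sample, "tumor"),
                            depth=int(depth),
                            alt_count=alt_count,
                            af=alt_count / depth if depth else 0.0,
                            gq=float(gq) if gq is not None else np.nan,
                            vqsr=float(vqsr) if vqsr is not None else np.nan,
                            in_1000g=bool(rec.info.get("KG1000", False)) if "KG1000" in declared else False,
                            in_esp=bool(rec.info.get("ESP", False)) if "ESP" in declared else False,
                            in_segdup=bool(rec.info.get("SEGDUP", False)) if "SEGDUP" in declared else False,
                            is_multiallelic=multi,
                        )
                    )
            except (TypeError, ValueError, IndexError) as exc:
                raise ValueError(f"malformed VCF record at data line {lineno}: {exc}") from exc
    return pd.DataFrame(rows).set_index("record_id") if rows else pd.DataFrame()


def write_vcf_minimal(records: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format variant table as an uncompressed VCF v4.2 file.

    Rows sharing (chrom, pos, ref, alt) become one record with one genotype
    column per ``sample_id``.
    """
    records = records.reset_index(drop=True)
    samples = sorted(records["sample_id"].unique())
    header = pysam.VariantHeader()
    for chrom in sorted(records["chrom"].astype(str).unique(), key=_chrom_key):
        header.contigs.add(chrom)
    for kind, name, number, vtype, desc in _VCF_HEADER_LINES:
        line = f'##{kind}=<ID={name},Number={number},Type={vtype},Description="{desc}">'
        header.add_line(line)
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        keys = ["chrom", "pos", "ref", "alt"]
        for (chrom, pos, ref, alt), group in records.groupby(keys, sort=True):
            rec = out.new_record(
                contig=str(chrom), start=int(pos) - 1, alleles=(str(ref), str(alt))
            )
            first = group.iloc[0]
            if pd.notna(first.get("vqsr")):
                rec.info["VQSR"] = float(first["vqsr"])
            for flag, info_key in (("in_1000g", "KG1000"), ("in_esp", "ESP"), ("in_segdup", "SEGDUP")):
                if bool(first.get(flag, False)):
                    rec.info[info_key] = True
            per_sample = group.set_index("sample_id")
            for s in samples:
                if s in per_sample.index:
                    row = per_sample.loc[s]
                    depth = int(row["depth"])
                    alt_count = int(row["alt_count"])
                    rec.samples[s]["AD"] = (depth - alt_count, alt_count)
                    rec.samples[s]["DP"] = depth
                    if pd.notna(row.get("gq")):
                        rec.samples[s]["GQ"] = int(row["gq"])
            out.write(rec)


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


def read_observation_table(path: str | Path) -> pd.DataFrame:
    """Read a PyClone-style tab-separated mutation observation table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns: {sorted(missing)}")
    return df


def write_observation_table(observations: pd.DataFrame, path: str | Path) -> None:
    observations.to_csv(path, sep="\t", index=False, columns=OBSERVATION_COLUMNS)


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a copy-number segment table (chrom, start, end, major_cn, minor_cn).

    Intervals are 1-based inclusive.  Overlapping segments on one chromosome
    or segments with minor_cn > major_cn are rejected.
    """
    seg = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "major_cn", "minor_cn"}
    if missing := required - set(seg.columns):
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if (seg["minor_cn"] > seg["major_cn"]).any():
        raise ValueError("segment with minor_cn > major_cn")
    seg = seg.sort_values(["chrom", "start"], ignore_index=True)
    for _, group in seg.groupby("chrom"):
        if (group["start"].iloc[1:].to_numpy() <= group["end"].iloc[:-1].to_numpy()).any():
            raise ValueError("overlapping segments on one chromosome")
    return seg


def assign_copy_number(mutations: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Join mutations to segments by 1-based inclusive containment.

    Mutations outside every segment fall back to the diploid heterozygous
    state (major 1, minor 1) with a warning.
    """
    out = mutations.copy()
    majors = np.ones(len(out), dtype=int)
    minors = np.ones(len(out), dtype=int)
    unmatched = 0
    for i, (chrom, pos) in enumerate(zip(out["chrom"].astype(str), out["pos"])):
        seg = segments[
            (segments["chrom"].astype(str) == chrom)
            & (segments["start"] <= pos)
            & (segments["end"] >= pos)
        ]
        if len(seg):
            majors[i] = int(seg["major_cn"].iloc[0])
            minors[i] = int(seg["minor_cn"].iloc[0])
        else:
            unmatched += 1
    if unmatched:
        warnings.warn(f"{unmatched} mutations outside all segments; defaulting to major=1, minor=1")
    out["major_cn"] = majors
    out["minor_cn"] = minors
    return out


def attach_matched_normal_af(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``matched_normal_af`` on tumor-role rows from normal-role rows
    sharing (chrom, pos, ref, alt); sites without a normal record get 0."""
    out = records.copy()
    keys = ["chrom", "pos", "ref", "alt"]
    normals = out[out["role"] == "normal"]
    if normals.empty:
        return out
    af = normals["alt_count"] / normals["depth"].where(normals["depth"] > 0, 1)
    normal_af = af.groupby([normals[k] for k in keys]).max()
    tumor_mask = out["role"] == "tumor"
    idx = pd.MultiIndex.from_frame(out.loc[tumor_mask, keys])
    out.loc[tumor_mask, "matched_normal_af"] = normal_af.reindex(idx).fillna(0.0).to_numpy()
    return out


def to_bed_interval(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to BED 0-based half-open."""
    return start_1based - 1, end_1based_inclusive
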