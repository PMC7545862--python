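"""Readers/writers for the formats the pipeline touches.

The VCF dialect written here is deliberately narrow and round-trip
exact: VCFv4.2, INFO ``DP`` plus ``NEAR_GAP``/``NEAR_INDEL`` flags,
FORMAT ``GT:AD:DP``, QUAL printed with one decimal, contig header
lines, records sorted by (chrom, pos, alt).  Reading goes through
cyvcf2 and accepts any conformant VCF: multi-allelic ALT lines are
split into one record per alternative allele with AD decomposed, so all
downstream set logic is per-allele.

Gene intervals come from GFF3 (``gene`` features) or BED via pyranges;
BED's 0-based half-open coordinates are converted to the 1-based
inclusive convention used everywhere else in the package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .caller import CallSet, GenotypeCall, VariantRecord
from .contrast import GeneInterval

__all__ = ["VcfParseError", "read_vcf", "write_vcf", "read_gene_intervals"]


class VcfParseError(ValueError):
    pass


def write_vcf(calls: CallSet, path) -> None:
    """Write a call set in the package dialect (see module docstring)."""
    records = sorted(calls.records, key=lambda r: (r.chrom, r.pos, r.alt))
    contigs = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">',
        '##INFO=<ID=NEAR_GAP,Number=0,Type=Flag,Description="Site within the gap proximity window">',
        '##INFO=<ID=NEAR_INDEL,Number=0,Type=Flag,Description="Site within the INDEL proximity window">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Reference and alternative read counts">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(calls.genotype_ids),
    ]
    for r in records:
        info = f"DP={r.dp}"
        if r.near_gap:
            info += ";NEAR_GAP"
        if r.near_indel:
            info += ";NEAR_INDEL"
        cols = [
            r.chrom,
            str(r.pos),
            ".",
            r.ref,
            r.alt,
            f"{r.qual:.1f}",
            ".",
            info,
            "GT:AD:DP",
        ]
        for gid in calls.genotype_ids:
            # a record from a key-union scenario may lack some columns
            g = r.genotypes.get(gid, GenotypeCall("./.", (0, 0), 0))
            cols.append(f"{g.gt}:{g.ad[0]},{g.ad[1]}:{g.dp}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def _gt_string(alleles: list[int], alt_number: int) -> str:
    # decomposed biallelic view: this alt vs everything else as ref
    if any(a < 0 for a in alleles[:2]):
        return "./."
    a, b = alleles[0], alleles[1]
    coded = sorted(int(x == alt_number) for x in (a, b))
    return f"{coded[0]}/{coded[1]}"


def read_vcf(path, label: str | None = None) -> CallSet:
    """Read a VCF into a call set, splitting multi-allelic lines."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VcfParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    cs = CallSet(label=label or path.stem, genotype_ids=samples)
    for lineno, v in enumerate(vcf, 1):
        ad = v.format("AD")
        dp = v.format("DP")
        if ad is None:
            raise VcfParseError(f"{path}: record {lineno}: missing FORMAT/AD")
        if ad.shape[1] != len(v.ALT) + 1:
            raise VcfParseError(
                f"{path}: record {lineno}: AD arity {ad.shape[1]} does not match "
                f"{len(v.ALT) + 1} alleles"
            )
        for i, alt in enumerate(v.ALT):
            genotypes = {}
            for s_idx, sample in enumerate(samples):
                ref_n = int(max(ad[s_idx, 0], 0))
                alt_n = int(max(ad[s_idx, i + 1], 0))
                g_dp = (
                    int(np.asarray(dp[s_idx]).reshape(-1)[0])
                    if dp is not None
                    else ref_n + alt_n
                )
                genotypes[sample] = GenotypeCall(
                    gt=_gt_string(v.genotypes[s_idx], i + 1),
                    ad=(ref_n, alt_n),
                    dp=max(g_dp, 0),
                )
            cs.records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                    dp=sum(g.dp for g in genotypes.values()),
                    near_gap=bool(v.INFO.get("NEAR_GAP", False)),
                    near_indel=bool(v.INFO.get("NEAR_INDEL", False)),
                    genotypes=genotypes,
                )
            )
    return cs


def read_gene_intervals(path, format: str) -> list[GeneInterval]:
    """Read gene intervals from GFF3 (``gene`` features) or BED.

    Both are returned 1-based inclusive; pyranges normalises input to
    0-based half-open, so start is shifted by +1 here.  Zero-length
    intervals (BED start == end) are rejected.
    """
    import pyranges as pr

    fmt = format.upper()
    if fmt == "GFF3":
        df = pr.read_gff3(str(path)).df
        df = df[df["Feature"] == "gene"]
        id_col = "ID" if "ID" in df.columns else "gene_id"
        if id_col not in df.columns:
            raise VcfParseError(f"{path}: GFF3 gene features lack ID attributes")
        names = df[id_col]
    elif fmt == "BED":
        df = pr.read_bed(str(path)).df
        if "Name" not in df.columns:
            raise VcfParseError(f"{path}: BED needs >= 4 columns (name required)")
        names = df["Name"]
    else:
        raise ValueError(f"unknown gene interval format: {format!r}")

    intervals = []
    for name, chrom, start0, end, strand in zip(
        names,
        df["Chromosome"].astype(str),
        df["Start"].astype(int),
        df["End"].astype(int),
        df["Strand"].astype(str) if "Strand" in df.columns else np.repeat(".", len(df)),
    ):
        if start0 >= end:
            raise ValueError(
                f"{path}: zero- or negative-length interval for {name} "
                f"({start0}..{end} in 0-based half-open coordinates)"
            )
        intervals.append(
            GeneInterval(
                gene_id=str(name), chrom=chrom, start=start0 + 1, end=end, strand=strand
            )
        )
    return intervals
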