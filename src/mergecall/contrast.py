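"""Fixed-within-group SNP identification and gene-level summaries.

Given a two-genotype call set (one pooled genotype per RFI group), a
variant is *present* in a group when that group's genotype carries at
least one alternative allele; hom-ref and missing ("./.") both count as
absent.  The call set then splits into variants unique to the low-RFI
group, unique to the high-RFI group, and shared — the three files the
group contrast produces.  Downstream, variants are filtered by
functional impact category, assigned to genes by position, and
summarised as SNPs per gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .caller import CallSet
from .cohort import Group
from .compare import VariantKey
from .rounding import round_half_away

__all__ = [
    "GroupPartition",
    "GeneInterval",
    "IMPACT_CATEGORIES",
    "DEFAULT_KEEP_IMPACTS",
    "identify_fixed_variants",
    "filter_by_impact",
    "assign_genes",
    "snps_per_gene",
    "read_impact_table",
]

IMPACT_CATEGORIES = frozenset({"HIGH", "MODERATE", "MODIFIER", "LOW"})
# the analysis keeps protein-affecting and non-coding-gene variants
DEFAULT_KEEP_IMPACTS = frozenset({"HIGH", "MODERATE", "MODIFIER"})


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class GroupPartition:
    """unique-low / unique-high / shared split of a two-group call set."""

    unique_low: set[VariantKey]
    unique_high: set[VariantKey]
    shared: set[VariantKey]

    @property
    def n_unique_low(self) -> int:
        return len(self.unique_low)

    @property
    def n_unique_high(self) -> int:
        return len(self.unique_high)

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def total(self) -> int:
        return self.n_unique_low + self.n_shared + self.n_unique_high

    def validate(self) -> None:
        if (
            self.unique_low & self.unique_high
            or self.unique_low & self.shared
            or self.unique_high & self.shared
        ):
            raise AssertionError("partition sets overlap")


def _present(gt: str) -> bool:
    return "1" in gt


def identify_fixed_variants(
    calls: CallSet,
    low_label: str = Group.LOW_RFI.value,
    high_label: str = Group.HIGH_RFI.value,
) -> GroupPartition:
    """Split a two-genotype call set by group presence of the alt allele.

    Records present in neither group (possible when both genotypes are
    hom-ref or missing on an emitted multi-allelic line) are excluded
    from all three sets with a warning.
    """
    if len(calls.genotype_ids) != 2:
        raise ValueError(
            f"expected exactly 2 group genotypes, got {len(calls.genotype_ids)}"
        )
    if set(calls.genotype_ids) != {low_label, high_label}:
        raise ValueError(
            f"genotype labels {calls.genotype_ids} do not match "
            f"({low_label!r}, {high_label!r})"
        )
    unique_low: set[VariantKey] = set()
    unique_high: set[VariantKey] = set()
    shared: set[VariantKey] = set()
    n_neither = 0
    for record in calls.records:
        in_low = _present(record.genotypes[low_label].gt)
        in_high = _present(record.genotypes[high_label].gt)
        key = VariantKey(*record.key)
        if in_low and in_high:
            shared.add(key)
        elif in_low:
            unique_low.add(key)
        elif in_high:
            unique_high.add(key)
        else:
            n_neither += 1
    if n_neither:
        warnings.warn(
            f"{n_neither} record(s) with the alt allele absent from both groups "
            "excluded from the partition"
        )
    part = GroupPartition(unique_low=unique_low, unique_high=unique_high, shared=shared)
    part.validate()
    return part


def read_impact_table(path) -> pd.DataFrame:
    """Read a variant-impact TSV: chrom pos ref alt gene_id consequence impact."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "ref", "alt", "gene_id", "consequence", "impact"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"impact table missing columns: {missing}")
    _check_impacts(table)
    return table


def _check_impacts(table: pd.DataFrame) -> None:
    bad = set(table["impact"].unique()) - IMPACT_CATEGORIES
    if bad:
        raise ValueError(f"unknown impact categories: {sorted(bad)}")


def filter_by_impact(
    variants: set[VariantKey],
    impacts: pd.DataFrame,
    keep: frozenset[str] = DEFAULT_KEEP_IMPACTS,
) -> tuple[set[VariantKey], int]:
    """Keep variants with any annotation in ``keep``.

    Variants absent from the impact table are dropped (the analysis
    proceeds only on annotated variants); the count of unannotated
    variants is returned alongside the filtered set.
    """
    if not keep:
        raise ValueError("keep set is empty")
    unknown = set(keep) - IMPACT_CATEGORIES
    if unknown:
        raise ValueError(f"unknown impact categories in keep: {sorted(unknown)}")
    _check_impacts(impacts)
    annotated: dict[VariantKey, set[str]] = {}
    for row in impacts.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        annotated.setdefault(key, set()).add(row.impact)
    kept = {
        v for v in variants if v in annotated and annotated[v] & keep
    }
    n_unannotated = sum(1 for v in variants if v not in annotated)
    return kept, n_unannotated


def assign_genes(
    variants: set[VariantKey], genes: list[GeneInterval]
) -> dict[VariantKey, set[str]]:
    """Map each variant to every gene whose interval contains its position.

    Containment is strict (1-based inclusive bounds), strand-agnostic,
    with no up/downstream flank; unmapped variants map to the empty set.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes [start, end] inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    return {
        v: {iv.data for iv in trees.get(v.chrom, IntervalTree())[v.pos]}
        for v in variants
    }


def snps_per_gene(mapping: dict[VariantKey, set[str]]) -> tuple[float, float]:
    """Mean and sample SD of SNP counts over genes with >= 1 assigned SNP."""
    counts: dict[str, int] = {}
    for gene_ids in mapping.values():
        for g in gene_ids:
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        raise ValueError("no gene received a SNP")
    values = np.array(list(counts.values()), dtype=float)
    sd = 0.0 if values.size == 1 else float(np.std(values, ddof=1))
    return round_half_away(float(values.mean()), 3), round_half_away(sd, 3)
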