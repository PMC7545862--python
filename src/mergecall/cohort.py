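"""Synthetic RNA-seq pileup cohort generator.

Emulates the study design the pipeline comparison assumes: two divergent
feed-efficiency groups (low/high residual feed intake, RFI) with six
animals each, each animal sampled in liver and muscle, so a full cohort
holds 2 groups x 2 tissues x ``n_per_group_per_tissue`` per-sample pileup
tables.  Every site carries a known truth label (group-fixed, shared
polymorphic, rare singleton, or invariant) so that caller sensitivity and
the fixed-within-group contrast can be scored exactly.

The generator works at the pileup level: per sample and site it draws a
read depth and an alternative-read count.  No reads, base qualities or
alignments are simulated; gap and INDEL proximity — which the downstream
filters consume only as predicates — are boolean context flags on sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Tissue",
    "VariantClass",
    "SampleMeta",
    "CohortConfig",
    "CohortConfigError",
    "TruthParseError",
    "simulate_cohort",
    "write_truth",
    "read_truth",
    "largest_remainder_allocation",
    "TRUTH_FIXED_COLUMNS",
]


class Group(str, Enum):
    """Phenotype group label: low RFI = more feed-efficient."""

    LOW_RFI = "LOW_RFI"
    HIGH_RFI = "HIGH_RFI"


class Tissue(str, Enum):
    LIVER = "LIVER"
    MUSCLE = "MUSCLE"


class VariantClass(str, Enum):
    """Truth class of a simulated site.

    FIXED_LOW / FIXED_HIGH: alternative allele fixed (dosage 2) in every
    animal of one group and absent from the other — the contrast the
    fixed-SNP identification stage must recover.
    SHARED_POLY: segregating in both groups under Hardy-Weinberg with a
    mid-range allele frequency.
    RARE_SINGLETON: heterozygous in exactly one animal — the class that
    pooled calling dilutes.
    INVARIANT: no true variation; alternative reads arise only from
    sequencing error.
    """

    FIXED_LOW = "FIXED_LOW"
    FIXED_HIGH = "FIXED_HIGH"
    SHARED_POLY = "SHARED_POLY"
    RARE_SINGLETON = "RARE_SINGLETON"
    INVARIANT = "INVARIANT"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: Group
    tissue: Tissue

    @property
    def animal_id(self) -> str:
        # sample ids are "<animal>_<tissue>"
        return self.sample_id.rsplit("_", 1)[0]


class CohortConfigError(ValueError):
    """Invalid cohort configuration; message names the offending field."""


class TruthParseError(ValueError):
    """Malformed truth table file; message carries the line number."""


_CLASS_ORDER = [
    VariantClass.FIXED_LOW,
    VariantClass.FIXED_HIGH,
    VariantClass.SHARED_POLY,
    VariantClass.RARE_SINGLETON,
    VariantClass.INVARIANT,
]


def _default_proportions() -> dict[VariantClass, float]:
    # Shared mid-frequency variants dominate real call sets; fixed and
    # rare classes are the minority of scientific interest.
    return {
        VariantClass.FIXED_LOW: 0.05,
        VariantClass.FIXED_HIGH: 0.05,
        VariantClass.SHARED_POLY: 0.55,
        VariantClass.RARE_SINGLETON: 0.15,
        VariantClass.INVARIANT: 0.20,
    }


@dataclass
class CohortConfig:
    """Study-condition knobs for the simulated cohort.

    ``mean_depth_liver`` is reads/site for an average-expression gene in
    liver; muscle depth is ``muscle_depth_ratio`` times that, reflecting
    the higher uniquely-mapped read yield of muscle libraries.
    ``expression_dispersion`` is the log-scale SD of a per-gene coverage
    factor shared by all sites of a gene.  ``error_rate`` is the per-read
    miscall probability used when drawing alternative reads.
    """

    n_per_group_per_tissue: int = 6
    n_sites: int = 1000
    mean_depth_liver: float = 10.0
    muscle_depth_ratio: float = 2.3
    expression_dispersion: float = 0.5
    error_rate: float = 0.01
    class_proportions: dict[VariantClass, float] = field(
        default_factory=_default_proportions
    )
    gap_fraction: float = 0.05
    indel_fraction: float = 0.05
    n_genes: int = 100
    site_spacing: int = 10
    chrom: str = "1"
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_per_group_per_tissue", "n_sites", "n_genes", "site_spacing"):
            if int(getattr(self, name)) <= 0:
                raise CohortConfigError(f"{name} must be a positive count")
        for name in ("mean_depth_liver", "muscle_depth_ratio"):
            if getattr(self, name) <= 0:
                raise CohortConfigError(f"{name} must be > 0")
        if self.expression_dispersion < 0:
            raise CohortConfigError("expression_dispersion must be >= 0")
        for name in ("error_rate", "gap_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{name} must lie in [0, 1]")
        props = self.class_proportions
        unknown = set(props) - set(_CLASS_ORDER)
        if unknown:
            raise CohortConfigError(
                f"class_proportions contains unknown classes: {sorted(unknown)}"
            )
        if any(p < 0 for p in props.values()):
            raise CohortConfigError("class_proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise CohortConfigError("class_proportions must sum to 1")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def largest_remainder_allocation(proportions: Sequence[float], total: int) -> list[int]:
    """Deterministically split ``total`` into integer counts ~ proportions.

    Floors the exact shares, then hands remaining units to the largest
    fractional remainders (ties broken by position).  Exact by
    construction: the counts always sum to ``total``.
    """
    exact = [p * total for p in proportions]
    counts = [math.floor(e) for e in exact]
    short = total - sum(counts)
    remainders = sorted(
        range(len(exact)), key=lambda i: (-(exact[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def build_samples(n_per_group_per_tissue: int) -> list[SampleMeta]:
    """Sample sheet for the 2-group x 2-tissue design.

    Each animal appears once per tissue; its two samples share the
    animal-level genotype.
    """
    samples = []
    for tissue in (Tissue.LIVER, Tissue.MUSCLE):
        for group, tag in ((Group.LOW_RFI, "low"), (Group.HIGH_RFI, "high")):
            for i in range(1, n_per_group_per_tissue + 1):
                samples.append(
                    SampleMeta(f"{tag}{i}_{tissue.value.lower()}", group, tissue)
                )
    return samples


_BASES = np.array(list("ACGT"))


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[SampleMeta], pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: sample sheet, tidy pileup table, truth table.

    Pileups are one row per (sample, site) with ref/alt read counts:
    depth ~ Poisson(tissue mean x per-gene log-normal factor) and
    alt_count ~ Binomial(depth, p) with
    p = (dosage/2)(1 - eps) + (1 - dosage/2) eps, eps = error_rate.
    Zero-depth cells are retained.  Fully reproducible given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    samples = build_samples(config.n_per_group_per_tissue)
    animals = sorted({s.animal_id for s in samples}, key=lambda a: (a.startswith("high"), a))
    low_animals = [a for a in animals if a.startswith("low")]
    high_animals = [a for a in animals if a.startswith("high")]

    pos = 1 + config.site_spacing * np.arange(n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4  # distinct from ref

    # deterministic class counts, random placement across sites
    counts = largest_remainder_allocation(
        [config.class_proportions.get(c, 0.0) for c in _CLASS_ORDER], n
    )
    labels = np.repeat([c.value for c in _CLASS_ORDER], counts)
    labels = labels[rng.permutation(n)]

    gene_idx = (np.arange(n) * config.n_genes) // n
    gene_ids = np.array([f"gene{g + 1:04d}" for g in gene_idx])
    gene_factor = rng.lognormal(
        mean=0.0, sigma=config.expression_dispersion, size=config.n_genes
    )

    near_gap = np.zeros(n, dtype=bool)
    near_gap[rng.choice(n, size=round(config.gap_fraction * n), replace=False)] = True
    near_indel = np.zeros(n, dtype=bool)
    near_indel[
        rng.choice(n, size=round(config.indel_fraction * n), replace=False)
    ] = True

    # animal-level dosage matrix, sites x animals
    dosage = np.zeros((n, len(animals)), dtype=np.int64)
    a_index = {a: j for j, a in enumerate(animals)}
    low_cols = [a_index[a] for a in low_animals]
    high_cols = [a_index[a] for a in high_animals]
    for i in range(n):
        cls = labels[i]
        if cls == VariantClass.FIXED_LOW.value:
            dosage[i, low_cols] = 2
        elif cls == VariantClass.FIXED_HIGH.value:
            dosage[i, high_cols] = 2
        elif cls == VariantClass.SHARED_POLY.value:
            f = rng.uniform(0.2, 0.8)
            dosage[i, :] = rng.binomial(2, f, size=len(animals))
        elif cls == VariantClass.RARE_SINGLETON.value:
            dosage[i, rng.integers(0, len(animals))] = 1

    truth = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "class": labels,
            "gene_id": gene_ids,
            "near_gap": near_gap,
            "near_indel": near_indel,
        }
    )
    for s in samples:
        truth[s.sample_id] = dosage[:, a_index[s.animal_id]]

    site_mean = gene_factor[gene_idx] * config.mean_depth_liver
    eps = config.error_rate
    frames = []
    for s in samples:
        mean = site_mean * (
            config.muscle_depth_ratio if s.tissue is Tissue.MUSCLE else 1.0
        )
        depth = rng.poisson(mean)
        dos = dosage[:, a_index[s.animal_id]].astype(float)
        p = (dos / 2.0) * (1.0 - eps) + (1.0 - dos / 2.0) * eps
        alt = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "chrom": config.chrom,
                    "pos": pos,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "ref_count": depth - alt,
                    "alt_count": alt,
                    "near_gap": near_gap,
                    "near_indel": near_indel,
                }
            )
        )
    pileups = pd.concat(frames, ignore_index=True)
    return samples, pileups, truth


TRUTH_FIXED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "class",
    "gene_id",
    "near_gap",
    "near_indel",
]


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the truth table as TSV, one row per site, one dosage column per sample."""
    if truth is None or len(truth) == 0:
        raise ValueError("truth table is empty")
    missing = [c for c in TRUTH_FIXED_COLUMNS if c not in truth.columns]
    if missing:
        raise ValueError(f"truth table missing columns: {missing}")
    out = truth.copy()
    out["near_gap"] = out["near_gap"].astype(int)
    out["near_indel"] = out["near_indel"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    """Read a truth TSV written by :func:`write_truth` (round-trip identity)."""
    path = Path(path)
    try:
        truth = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.ParserError as exc:  # pandas reports the bad line
        raise TruthParseError(f"{path}: {exc}") from exc
    missing = [c for c in TRUTH_FIXED_COLUMNS if c not in truth.columns]
    if missing:
        raise TruthParseError(f"{path}: line 1: missing columns {missing}")
    if len(truth) == 0:
        raise TruthParseError(f"{path}: no data rows")
    if not np.issubdtype(truth["pos"].dtype, np.integer):
        bad = truth.index[pd.to_numeric(truth["pos"], errors="coerce").isna()]
        line = (bad[0] + 2) if len(bad) else 2
        raise TruthParseError(f"{path}: line {line}: non-integer position")
    truth["near_gap"] = truth["near_gap"].astype(bool)
    truth["near_indel"] = truth["near_indel"].astype(bool)
    return truth
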