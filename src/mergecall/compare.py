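"""Comparison statistics between approach call sets.

Four analyses, each answering one question about two (or more) call
sets produced by different sample-merging approaches:

* :func:`partition_variants` — three-way unique/shared/unique split of
  the variant keys of two call sets, with percentages;
* :func:`depth_summary` — order statistics of per-variant read depth;
* :func:`cohens_d_qual` — standardized mean difference of site QUAL
  between two call sets, unequal-variance (Welch) denominator
  ``sqrt((s_a^2 + s_b^2) / 2)``;
* :func:`aaf_sharing_curve` — fraction of a reference call set's
  variants also found in another set, binned by genotype-based
  alternative allele frequency (rising curves show that low-frequency
  variants are the ones merging approaches disagree on).

A variant is keyed by (chrom, pos, ref, alt): the same position with a
different alternative allele is a different variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .caller import CallSet
from .rounding import round_half_away

__all__ = [
    "VariantKey",
    "ComparisonResult",
    "DepthSummary",
    "AAFSharingCurve",
    "partition_variants",
    "mean_shared_percentage",
    "depth_summary",
    "cohens_d_qual",
    "aaf_sharing_curve",
    "genotype_aaf",
]


class VariantKey(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class ComparisonResult:
    """One unique-A / shared / unique-B partition row."""

    label_a: str
    label_b: str
    n_unique_a: int
    n_shared: int
    n_unique_b: int
    pct_unique_a: float
    pct_shared: float
    pct_unique_b: float

    @property
    def total(self) -> int:
        return self.n_unique_a + self.n_shared + self.n_unique_b


@dataclass(frozen=True)
class DepthSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float
    sd: float


@dataclass(frozen=True)
class AAFSharingCurve:
    bin_edges: tuple[float, ...]  # len = n_bins + 1, spans [0, 1]
    n_variants: tuple[int, ...]
    pct_shared: tuple[float, ...]  # NaN for empty bins


def _keys(calls: CallSet | Iterable[VariantKey], side: str) -> set[VariantKey]:
    if isinstance(calls, CallSet):
        keys = [VariantKey(*r.key) for r in calls.records]
    else:
        keys = [VariantKey(*k) for k in calls]
    unique = set(keys)
    if len(unique) != len(keys):
        warnings.warn(f"duplicate variant keys in set {side} collapsed")
    return unique


def partition_variants(
    a: CallSet | Iterable[VariantKey],
    b: CallSet | Iterable[VariantKey],
    label_a: str | None = None,
    label_b: str | None = None,
) -> ComparisonResult:
    """Exact three-way set partition of two call sets by variant key."""
    ka = _keys(a, "A")
    kb = _keys(b, "B")
    label_a = label_a or (a.label if isinstance(a, CallSet) else "A")
    label_b = label_b or (b.label if isinstance(b, CallSet) else "B")
    n_ua, n_sh, n_ub = len(ka - kb), len(ka & kb), len(kb - ka)
    total = n_ua + n_sh + n_ub
    if total == 0:
        raise ValueError("both call sets are empty")
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        n_unique_a=n_ua,
        n_shared=n_sh,
        n_unique_b=n_ub,
        pct_unique_a=round_half_away(100.0 * n_ua / total, 2),
        pct_shared=round_half_away(100.0 * n_sh / total, 2),
        pct_unique_b=round_half_away(100.0 * n_ub / total, 2),
    )


def mean_shared_percentage(results: list[ComparisonResult]) -> float:
    """Arithmetic mean of the shared percentages, two decimals."""
    if not results:
        raise ValueError("no comparison results supplied")
    return round_half_away(float(np.mean([r.pct_shared for r in results])), 2)


def depth_summary(calls: CallSet) -> DepthSummary:
    """Per-variant read-depth order statistics for one call set.

    Quantiles use linear interpolation between order statistics; SD is
    the sample SD (n-1), 0 by convention for a single record.
    """
    if len(calls) == 0:
        raise ValueError(f"call set {calls.label!r} is empty")
    dp = calls.depths()
    q1, med, q3 = np.percentile(dp, [25, 50, 75])
    sd = 0.0 if dp.size == 1 else float(np.std(dp, ddof=1))
    return DepthSummary(
        minimum=float(dp.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(dp.max()),
        mean=float(dp.mean()),
        sd=sd,
    )


def cohens_d_qual(a: CallSet, b: CallSet) -> float:
    """Cohen's d for the Welch comparison of site QUAL, |d| to 3 decimals.

    Uses the unequal-variance denominator sqrt((s_a^2 + s_b^2)/2) with
    sample variances; the magnitude is reported.
    """
    qa, qb = a.quals(), b.quals()
    if qa.size < 2 or qb.size < 2:
        raise ValueError("Cohen's d needs at least 2 records per call set")
    va, vb = np.var(qa, ddof=1), np.var(qb, ddof=1)
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0:
        raise ValueError("zero QUAL variance in both call sets")
    return round_half_away(float(abs(qa.mean() - qb.mean()) / denom), 3)


def genotype_aaf(record) -> float | None:
    """Genotype-based AAF: alt allele dosage over 2 x non-missing genotypes."""
    alt_alleles = 0
    called = 0
    for g in record.genotypes.values():
        if g.gt == "./.":
            continue
        called += 1
        alt_alleles += g.gt.count("1")
    if called == 0:
        return None
    return alt_alleles / (2.0 * called)


def aaf_sharing_curve(
    reference: CallSet,
    other: CallSet | Iterable[VariantKey],
    bin_width: float = 0.1,
) -> AAFSharingCurve:
    """Sharing percentage of the reference set's variants, by AAF bin.

    The reference set must carry called genotypes; each of its variants
    is binned by genotype-based AAF, and per bin the percentage whose
    key also occurs in ``other`` is reported.  The last bin is closed at
    1.0.  ``bin_width`` must divide 1 evenly.
    """
    if len(reference) == 0:
        raise ValueError("reference call set is empty")
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError("bin_width must divide 1 evenly")
    other_keys = _keys(other, "other")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    shared = np.zeros(n_bins, dtype=int)
    for record in reference.records:
        aaf = genotype_aaf(record)
        if aaf is None:
            warnings.warn(
                f"all genotypes missing at {record.chrom}:{record.pos}; record skipped"
            )
            continue
        b = min(int(aaf / bin_width), n_bins - 1)
        counts[b] += 1
        if VariantKey(*record.key) in other_keys:
            shared[b] += 1
    pct = tuple(
        round_half_away(100.0 * s / c, 2) if c else float("nan")
        for s, c in zip(shared, counts)
    )
    return AAFSharingCurve(
        bin_edges=tuple(edges.tolist()),
        n_variants=tuple(counts.tolist()),
        pct_shared=pct,
    )
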