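"""Simplified multi-sample (joint) genotype-likelihood caller.

Converts per-genotype pileups — individual samples or pooled
pseudo-samples — into VCF-style variant records with QUAL, DP, GT and AD.
The model is deliberately minimal but mechanistically faithful to what a
joint caller does to merged files:

* every genotype column is diploid, including pools of many animals;
* per genotype, the read counts are binomial given the dosage
  g in {0, 1, 2}: ``alt_count ~ Binomial(depth, p_g)`` with
  ``p_g = (g/2)(1 - eps) + (1 - g/2) eps``;
* a flat prior (1/3 each) gives genotype posteriors;
* site quality is the Phred-scaled probability that *no* genotype
  carries the alternative allele:
  ``QUAL = -10 * sum_s log10 P(g_s = 0 | data)`` over informative
  (depth > 0) genotypes, capped at 10,000.

Two consequences of this model reproduce the phenomena that make the
merging comparison interesting: *dilution* (a singleton carrier's reads
pooled among many reference reads are best explained as hom-ref plus
sequencing error, so the pooled site is not emitted) and *QUAL
inflation* (each additional alt-carrying genotype multiplies the
product of hom-ref posteriors by a factor < 1, so QUAL never decreases
with carrier count).

All likelihood work is done in log space; a brute-force linear-space
oracle is used in the test suite to validate it at small depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .pileup import PoolingScheme, pool_pileups

__all__ = [
    "GenotypeLikelihoods",
    "GenotypeCall",
    "VariantRecord",
    "CallSet",
    "genotype_likelihoods",
    "call_site",
    "call_variants",
    "DEFAULT_EMIT_THRESHOLD",
    "QUAL_CAP",
]

# Phred 3.0103 == posterior probability of "any variant" just above 0.5
DEFAULT_EMIT_THRESHOLD = 3.0103
QUAL_CAP = 10_000.0
_LN10 = np.log(10.0)


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """Log-likelihoods and flat-prior posteriors for dosages 0/1/2.

    A zero-depth genotype is uninformative: posteriors are the flat
    prior and the genotype contributes factor 1 to site quality.
    """

    log_likelihoods: tuple[float, float, float]
    posteriors: tuple[float, float, float]
    informative: bool


@dataclass(frozen=True)
class GenotypeCall:
    gt: str  # "0/0", "0/1", "1/1" or "./."
    ad: tuple[int, int]
    dp: int


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    dp: int
    near_gap: bool
    near_indel: bool
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def alt_reads(self) -> int:
        return sum(g.ad[1] for g in self.genotypes.values())


@dataclass
class CallSet:
    """Named collection of variant records for one approach scenario."""

    label: str
    genotype_ids: list[str]
    records: list[VariantRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {r.key for r in self.records}

    def quals(self) -> np.ndarray:
        return np.array([r.qual for r in self.records], dtype=float)

    def depths(self) -> np.ndarray:
        return np.array([r.dp for r in self.records], dtype=float)


def _validate_eps(eps: float) -> None:
    if not 0.0 < eps < 0.5:
        raise ValueError(f"error rate must lie in (0, 0.5), got {eps}")


def _loglik_matrix(ref: np.ndarray, alt: np.ndarray, eps: float) -> np.ndarray:
    """Binomial log-likelihoods, shape (..., 3) for dosage 0/1/2."""
    n = ref + alt
    k = alt
    logchoose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    out = np.empty(n.shape + (3,), dtype=float)
    for g in range(3):
        p = (g / 2.0) * (1.0 - eps) + (1.0 - g / 2.0) * eps
        out[..., g] = logchoose + k * np.log(p) + (n - k) * np.log1p(-p)
    return out


def genotype_likelihoods(
    ref_count: int, alt_count: int, error_rate: float = 0.01
) -> GenotypeLikelihoods:
    """Dosage likelihoods for one genotype's pileup counts."""
    _validate_eps(error_rate)
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    if ref_count + alt_count == 0:
        third = 1.0 / 3.0
        return GenotypeLikelihoods((0.0, 0.0, 0.0), (third, third, third), False)
    ll = _loglik_matrix(np.array(ref_count), np.array(alt_count), error_rate)
    post = np.exp(ll - logsumexp(ll))
    return GenotypeLikelihoods(tuple(ll.tolist()), tuple(post.tolist()), True)


_GT_STRINGS = ("0/0", "0/1", "1/1")


def _call_arrays(
    ref: np.ndarray, alt: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised kernel: (sites x genotypes) counts -> (qual, gt index).

    Returns per-site QUAL and per-cell genotype index (0/1/2, or -1 for
    zero depth).
    """
    ll = _loglik_matrix(ref, alt, eps)  # (S, P, 3)
    norm = logsumexp(ll, axis=-1, keepdims=True)
    logpost = ll - norm
    informative = (ref + alt) > 0
    gt_idx = np.argmax(logpost, axis=-1)
    gt_idx = np.where(informative, gt_idx, -1)
    log10_post0 = np.where(informative, logpost[..., 0] / _LN10, 0.0)
    qual = np.minimum(-10.0 * log10_post0.sum(axis=-1), QUAL_CAP)
    return qual, gt_idx


def call_site(
    site: dict,
    genotype_counts: dict[str, tuple[int, int]],
    error_rate: float = 0.01,
    emit_threshold: float = DEFAULT_EMIT_THRESHOLD,
) -> VariantRecord | None:
    """Call one site from per-genotype (ref_count, alt_count) pairs.

    ``site`` supplies chrom, pos, ref, alt and optional near_gap /
    near_indel flags.  Returns the record if the site's QUAL reaches
    ``emit_threshold`` and at least one alternative read was observed;
    otherwise ``None``.
    """
    _validate_eps(error_rate)
    if not genotype_counts:
        raise ValueError("at least one genotype required")
    if site["ref"] == site["alt"]:
        raise ValueError("ref and alt must differ")
    labels = list(genotype_counts)
    ref = np.array([[genotype_counts[l][0] for l in labels]])
    alt = np.array([[genotype_counts[l][1] for l in labels]])
    qual, gt_idx = _call_arrays(ref, alt, error_rate)
    total_alt = int(alt.sum())
    if qual[0] < emit_threshold or total_alt < 1:
        return None
    genotypes = {
        l: GenotypeCall(
            gt=_GT_STRINGS[gt_idx[0, j]] if gt_idx[0, j] >= 0 else "./.",
            ad=(int(ref[0, j]), int(alt[0, j])),
            dp=int(ref[0, j] + alt[0, j]),
        )
        for j, l in enumerate(labels)
    }
    return VariantRecord(
        chrom=site["chrom"],
        pos=int(site["pos"]),
        ref=site["ref"],
        alt=site["alt"],
        qual=float(qual[0]),
        dp=int((ref + alt).sum()),
        near_gap=bool(site.get("near_gap", False)),
        near_indel=bool(site.get("near_indel", False)),
        genotypes=genotypes,
    )


def call_variants(
    pileups,
    scheme: PoolingScheme,
    error_rate: float = 0.01,
    emit_threshold: float = DEFAULT_EMIT_THRESHOLD,
    label: str | None = None,
) -> CallSet:
    """Pool pileups per ``scheme`` and jointly call every site.

    One multi-genotype record per emitted site, sites in
    (chrom, pos, alt) order; deterministic.
    """
    _validate_eps(error_rate)
    pool_ids = list(scheme.pools)
    cs = CallSet(label=label or scheme.approach.value, genotype_ids=pool_ids)
    if len(pileups) == 0:
        return cs
    pooled = pool_pileups(pileups, scheme)

    key_cols = ["chrom", "pos", "ref", "alt"]
    wide_ref = pooled.pivot_table(
        index=key_cols, columns="sample_id", values="ref_count", sort=True
    )[pool_ids]
    wide_alt = pooled.pivot_table(
        index=key_cols, columns="sample_id", values="alt_count", sort=True
    )[pool_ids]
    flags = (
        pooled.groupby(key_cols)[["near_gap", "near_indel"]].any().loc[wide_ref.index]
    )
    if wide_ref.isna().any().any() or wide_alt.isna().any().any():
        raise ValueError("site grids differ across pools")

    ref = wide_ref.to_numpy(dtype=np.int64)
    alt = wide_alt.to_numpy(dtype=np.int64)
    qual, gt_idx = _call_arrays(ref, alt, error_rate)
    emitted = (qual >= emit_threshold) & (alt.sum(axis=1) >= 1)

    sites = wide_ref.index.to_frame(index=False)
    # pivot sorts positions lexicographically; enforce numeric order
    chrom_order = np.lexsort(
        (sites["alt"].to_numpy(), sites["pos"].to_numpy(), sites["chrom"].to_numpy())
    )
    for i in chrom_order:
        if not emitted[i]:
            continue
        genotypes = {
            pid: GenotypeCall(
                gt=_GT_STRINGS[gt_idx[i, j]] if gt_idx[i, j] >= 0 else "./.",
                ad=(int(ref[i, j]), int(alt[i, j])),
                dp=int(ref[i, j] + alt[i, j]),
            )
            for j, pid in enumerate(pool_ids)
        }
        cs.records.append(
            VariantRecord(
                chrom=str(sites["chrom"].iloc[i]),
                pos=int(sites["pos"].iloc[i]),
                ref=str(sites["ref"].iloc[i]),
                alt=str(sites["alt"].iloc[i]),
                qual=float(qual[i]),
                dp=int(ref[i].sum() + alt[i].sum()),
                near_gap=bool(flags["near_gap"].iloc[i]),
                near_indel=bool(flags["near_indel"].iloc[i]),
                genotypes=genotypes,
            )
        )
    return cs
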