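"""Pileup pooling: merge per-sample read counts into pseudo-samples.

Three pooling approaches are compared throughout the package:

* ``NON_MERGED`` — every sample is its own genotype column (joint calling
  across individuals);
* ``MERGED_BY_GROUP_TISSUE`` — one pooled pseudo-sample per
  (RFI group, tissue), i.e. reads of the six animals of a group merged
  within each tissue;
* ``MERGED_BY_GROUP`` — one pooled pseudo-sample per RFI group, merging
  both tissues of all six animals.

Pooling is exactly additive in read counts (conservation of reads);
real merged BAM files deviate slightly because quality filtering is
re-applied after merging, a divergence documented in docs/methods.md.
Gap/INDEL proximity flags OR across members: a pool is near a feature if
any member is.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import SampleMeta, Tissue

__all__ = ["Approach", "PoolingScheme", "build_scheme", "pool_pileups", "PILEUP_COLUMNS"]

PILEUP_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "near_gap",
    "near_indel",
]


class Approach(str, Enum):
    NON_MERGED = "NON_MERGED"
    MERGED_BY_GROUP_TISSUE = "MERGED_BY_GROUP_TISSUE"
    MERGED_BY_GROUP = "MERGED_BY_GROUP"


@dataclass(frozen=True)
class PoolingScheme:
    """Disjoint cover of the cohort's samples by named pools."""

    approach: Approach
    pools: dict[str, tuple[str, ...]]

    def __post_init__(self):
        seen: set[str] = set()
        for pool_id, members in self.pools.items():
            if not members:
                raise ValueError(f"pool {pool_id!r} is empty")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"samples in more than one pool: {sorted(overlap)}")
            seen.update(members)

    @property
    def sample_ids(self) -> set[str]:
        return {s for members in self.pools.values() for s in members}


def build_scheme(
    samples: list[SampleMeta],
    approach: Approach,
    tissue_restriction: Tissue | None = None,
) -> PoolingScheme:
    """Build the pool layout for one approach.

    ``tissue_restriction`` limits the scheme to one tissue's samples and
    is only meaningful for NON_MERGED and MERGED_BY_GROUP_TISSUE (the
    by-group merge spans tissues by definition).
    """
    if not samples:
        raise ValueError("no samples supplied")
    approach = Approach(approach)
    if tissue_restriction is not None:
        if approach is Approach.MERGED_BY_GROUP:
            raise ValueError("tissue_restriction is invalid for MERGED_BY_GROUP")
        samples = [s for s in samples if s.tissue is Tissue(tissue_restriction)]
        if not samples:
            raise ValueError(f"no samples left after restricting to {tissue_restriction}")

    pools: dict[str, tuple[str, ...]] = {}
    if approach is Approach.NON_MERGED:
        pools = {s.sample_id: (s.sample_id,) for s in samples}
    elif approach is Approach.MERGED_BY_GROUP_TISSUE:
        for s in samples:
            pools.setdefault(f"{s.group.value}_{s.tissue.value}", [])  # type: ignore[arg-type]
        for s in samples:
            pools[f"{s.group.value}_{s.tissue.value}"].append(s.sample_id)  # type: ignore[union-attr]
        pools = {k: tuple(v) for k, v in pools.items()}
    else:  # MERGED_BY_GROUP
        grouped: dict[str, list[str]] = {}
        for s in samples:
            grouped.setdefault(s.group.value, []).append(s.sample_id)
        pools = {k: tuple(v) for k, v in grouped.items()}
    return PoolingScheme(approach=approach, pools=pools)


def pool_pileups(pileups: pd.DataFrame, scheme: PoolingScheme) -> pd.DataFrame:
    """Sum member read counts per pool and site; OR the proximity flags.

    Requires every pooled sample to be present with an identical site
    grid (chrom, pos, ref, alt); the output has ``pool_id`` in place of
    ``sample_id`` and one row per (pool, site).
    """
    present = set(pileups["sample_id"].unique())
    missing = scheme.sample_ids - present
    if missing:
        raise ValueError(f"samples missing from pileups: {sorted(missing)}")

    sub = pileups[pileups["sample_id"].isin(scheme.sample_ids)].copy()
    key_cols = ["chrom", "pos", "ref", "alt"]
    grids = sub.groupby("sample_id")[key_cols].apply(
        lambda df: tuple(map(tuple, df.sort_values(["chrom", "pos", "alt"]).values))
    )
    if grids.nunique() != 1:
        raise ValueError("site grids differ across pooled samples")

    pool_of = {s: pid for pid, members in scheme.pools.items() for s in members}
    sub["pool_id"] = sub["sample_id"].map(pool_of)
    pooled = (
        sub.groupby(["pool_id"] + key_cols, as_index=False, sort=False)
        .agg(
            ref_count=("ref_count", "sum"),
            alt_count=("alt_count", "sum"),
            near_gap=("near_gap", "any"),
            near_indel=("near_indel", "any"),
        )
        .rename(columns={"pool_id": "sample_id"})
    )
    return pooled[PILEUP_COLUMNS].sort_values(
        ["sample_id", "chrom", "pos", "alt"], ignore_index=True
    )
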