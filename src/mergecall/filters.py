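"""Six-rule variant filter cascade and pass-rate accounting.

A record survives only if it passes the full conjunction, applied in a
fixed order so each removal can be attributed to the first failing rule:

1. site read depth DP >= ``min_depth`` (default 10);
2. total alternative-supporting reads >= ``min_alt_reads`` (default 2);
3. not within ``gap_window`` bp of an alignment gap (default 3);
4. site QUAL >= ``min_qual`` (default 30, Phred);
5. not within ``indel_window`` bp of an INDEL (default 5);
6. site alternative allele frequency >= ``min_aaf`` (default 0.20),
   where the filter AAF is read-based: total alt reads / total reads.

Gap and INDEL proximity enter as per-record boolean flags: the windows
are properties of how the flags were produced (or simulated), the
cascade consumes only the predicate.  Total survivors are
order-invariant since the predicate is a conjunction; only the per-rule
attribution depends on the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caller import CallSet
from .rounding import round_half_away

__all__ = ["FilterConfig", "FilterReport", "apply_filters", "pass_rate_summary", "RULES"]

RULES = ("min_depth", "min_alt_reads", "gap", "min_qual", "indel", "min_aaf")


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 10
    min_alt_reads: int = 2
    gap_window: int = 3
    min_qual: float = 30.0
    indel_window: int = 5
    min_aaf: float = 0.20

    def __post_init__(self):
        for name in ("min_depth", "min_alt_reads", "gap_window", "indel_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if not 0.0 <= self.min_aaf <= 1.0:
            raise ValueError("min_aaf must lie in [0, 1]")


@dataclass
class FilterReport:
    """Before/after accounting for one approach scenario (one table row)."""

    label: str
    n_before: int
    n_after: int
    pct_pass: float
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "scenario": self.label,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "pct_pass": self.pct_pass,
        }
        row.update({f"removed_{r}": self.removed_by_rule.get(r, 0) for r in RULES})
        return row


def _first_failing_rule(record, config: FilterConfig) -> str | None:
    dp = record.dp
    alt_reads = record.alt_reads
    if dp < config.min_depth:
        return "min_depth"
    if alt_reads < config.min_alt_reads:
        return "min_alt_reads"
    if record.near_gap:
        return "gap"
    if record.qual < config.min_qual:
        return "min_qual"
    if record.near_indel:
        return "indel"
    aaf = alt_reads / dp if dp > 0 else 0.0
    if aaf < config.min_aaf:
        return "min_aaf"
    return None


def apply_filters(
    calls: CallSet, config: FilterConfig = FilterConfig()
) -> tuple[CallSet, FilterReport]:
    """Filter a call set; returns survivors (input order) and the report."""
    removed = {r: 0 for r in RULES}
    kept = []
    for record in calls.records:
        for attr in ("qual", "dp", "near_gap", "near_indel"):
            if getattr(record, attr, None) is None:
                raise ValueError(f"record at {record.chrom}:{record.pos} missing {attr}")
        rule = _first_failing_rule(record, config)
        if rule is None:
            kept.append(record)
        else:
            removed[rule] += 1
    n_before = len(calls.records)
    n_after = len(kept)
    pct = round_half_away(100.0 * n_after / n_before, 2) if n_before else 0.00
    report = FilterReport(
        label=calls.label,
        n_before=n_before,
        n_after=n_after,
        pct_pass=pct,
        removed_by_rule=removed,
    )
    filtered = CallSet(label=calls.label, genotype_ids=list(calls.genotype_ids), records=kept)
    return filtered, report


def pass_rate_summary(
    reports: list[FilterReport],
) -> tuple[list[float], float, float]:
    """Per-scenario pass percentages with their mean and sample SD.

    SD uses the n-1 denominator; a single report gives SD 0 by
    convention.  All three outputs are rounded half-away-from-zero to
    two decimals, matching how such tables are printed.
    """
    if not reports:
        raise ValueError("no reports supplied")
    if any(r.n_before <= 0 for r in reports):
        raise ValueError("pass_rate_summary requires n_before > 0 for every report")
    pcts = [r.pct_pass for r in reports]
    mean = round_half_away(float(np.mean(pcts)), 2)
    sd = 0.0 if len(pcts) == 1 else round_half_away(float(np.std(pcts, ddof=1)), 2)
    return pcts, mean, sd
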