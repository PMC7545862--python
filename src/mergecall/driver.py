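"""Run the full merging-approach comparison as one reproducible experiment.

Pipeline: simulate a cohort -> call variants under the three pooling
approaches -> apply the filter cascade -> compare the call sets
(set partitions, depth summaries, QUAL effect sizes, AAF-sharing
curves) -> contrast the by-group call set into fixed-within-group SNPs
-> score every scenario against the simulated truth.

Seven approach scenarios are produced: per-tissue non-merged calls
(``i_liver``, ``i_muscle``) and their key-union (``i_both``); per-tissue
by-group-and-tissue pools (``ii_liver``, ``ii_muscle``) and their union
(``ii_both``); and the by-group pool across tissues (``iii``).  The
combined-tissue scenarios are key-unions of the per-tissue call sets,
keeping the first scenario's record when a key occurs in both.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .caller import CallSet, call_variants
from .cohort import CohortConfig, SampleMeta, Tissue, VariantClass, simulate_cohort, write_truth
from .compare import (
    AAFSharingCurve,
    ComparisonResult,
    DepthSummary,
    aaf_sharing_curve,
    cohens_d_qual,
    depth_summary,
    mean_shared_percentage,
    partition_variants,
)
from .contrast import GroupPartition, identify_fixed_variants
from .filters import FilterConfig, FilterReport, apply_filters, pass_rate_summary
from .pileup import Approach, build_scheme
from .vcfio import write_vcf

__all__ = ["ExperimentBundle", "run_experiment", "union_callsets", "site_mean_depths", "SCENARIOS"]

SCENARIOS = ["i_liver", "i_muscle", "i_both", "ii_liver", "ii_muscle", "ii_both", "iii"]

# Table-2-style pairwise comparisons: per-tissue i vs ii, then each
# combined approach against the full merge.
COMPARISON_PAIRS = [
    ("i_liver", "ii_liver"),
    ("i_muscle", "ii_muscle"),
    ("i_both", "iii"),
    ("ii_both", "iii"),
]

# AAF-sharing panels: every non-iii scenario against approach iii.
CURVE_REFERENCES = ["i_liver", "i_muscle", "i_both", "ii_liver", "ii_muscle", "ii_both"]


def union_callsets(label: str, a: CallSet, b: CallSet) -> CallSet:
    """Key-union of two call sets; the first set's record wins on overlap."""
    seen = set()
    records = []
    for r in list(a.records) + list(b.records):
        if r.key in seen:
            continue
        seen.add(r.key)
        records.append(r)
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
    genotype_ids = list(a.genotype_ids) + [
        g for g in b.genotype_ids if g not in a.genotype_ids
    ]
    return CallSet(label=label, genotype_ids=genotype_ids, records=records)


def site_mean_depths(pileups: pd.DataFrame) -> pd.Series:
    """Mean per-sample read depth per site, indexed by (chrom, pos)."""
    depth = pileups["ref_count"] + pileups["alt_count"]
    return depth.groupby([pileups["chrom"], pileups["pos"]]).mean()


@dataclass
class ExperimentBundle:
    config: CohortConfig
    filter_config: FilterConfig
    samples: list[SampleMeta]
    pileups: pd.DataFrame
    truth: pd.DataFrame
    callsets: dict[str, CallSet]
    filtered: dict[str, CallSet]
    reports: dict[str, FilterReport]
    comparisons: list[ComparisonResult]
    depth_summaries: dict[str, DepthSummary]
    cohens_d: dict[tuple[str, str], float]
    aaf_curves: dict[str, AAFSharingCurve]
    partition: GroupPartition
    detection: pd.DataFrame = field(repr=False)

    @property
    def mean_shared_pct(self) -> float:
        return mean_shared_percentage(self.comparisons)


def _truth_keys_by_class(truth: pd.DataFrame) -> dict[str, set]:
    out: dict[str, set] = {c.value: set() for c in VariantClass}
    for chrom, pos, ref, alt, cls in zip(
        truth["chrom"], truth["pos"], truth["ref"], truth["alt"], truth["class"]
    ):
        out[cls].add((str(chrom), int(pos), ref, alt))
    return out


def _detection_table(
    truth: pd.DataFrame, filtered: dict[str, CallSet]
) -> pd.DataFrame:
    """Truth-based sensitivity per scenario and variant class.

    For INVARIANT sites the reported rate is the false-site rate (the
    fraction of truly invariant sites that survive calling+filtering),
    i.e. 1 - specificity.
    """
    by_class = _truth_keys_by_class(truth)
    rows = []
    for scenario, cs in filtered.items():
        detected = cs.keys()
        for cls, keys in by_class.items():
            n_truth = len(keys)
            n_det = len(keys & detected)
            rate = n_det / n_truth if n_truth else float("nan")
            rows.append(
                {
                    "scenario": scenario,
                    "class": cls,
                    "n_truth": n_truth,
                    "n_detected": n_det,
                    "rate": rate,
                    "rate_kind": "false_site_rate"
                    if cls == VariantClass.INVARIANT.value
                    else "sensitivity",
                }
            )
    return pd.DataFrame(rows)


def run_experiment(
    config: CohortConfig | None = None,
    filter_config: FilterConfig | None = None,
    out_dir: str | Path | None = None,
    call_error_rate: float | None = None,
) -> ExperimentBundle:
    """Execute the whole comparison; optionally write the report bundle.

    ``call_error_rate`` is the error rate the caller assumes; it
    defaults to the generator's rate, falling back to 0.01 when the
    cohort was generated noise-free (the caller requires 0 < eps < 0.5).
    """
    config = config or CohortConfig()
    filter_config = filter_config or FilterConfig()
    if call_error_rate is None:
        call_error_rate = config.error_rate if 0.0 < config.error_rate < 0.5 else 0.01

    samples, pileups, truth = simulate_cohort(config)

    def call(approach: Approach, tissue: Tissue | None, label: str) -> CallSet:
        scheme = build_scheme(samples, approach, tissue)
        return call_variants(pileups, scheme, call_error_rate, label=label)

    callsets = {
        "i_liver": call(Approach.NON_MERGED, Tissue.LIVER, "i_liver"),
        "i_muscle": call(Approach.NON_MERGED, Tissue.MUSCLE, "i_muscle"),
        "ii_liver": call(Approach.MERGED_BY_GROUP_TISSUE, Tissue.LIVER, "ii_liver"),
        "ii_muscle": call(Approach.MERGED_BY_GROUP_TISSUE, Tissue.MUSCLE, "ii_muscle"),
        "iii": call(Approach.MERGED_BY_GROUP, None, "iii"),
    }
    callsets["i_both"] = union_callsets("i_both", callsets["i_liver"], callsets["i_muscle"])
    callsets["ii_both"] = union_callsets("ii_both", callsets["ii_liver"], callsets["ii_muscle"])
    callsets = {s: callsets[s] for s in SCENARIOS}

    filtered: dict[str, CallSet] = {}
    reports: dict[str, FilterReport] = {}
    for scenario, cs in callsets.items():
        filtered[scenario], reports[scenario] = apply_filters(cs, filter_config)

    comparisons = [
        partition_variants(callsets[a], callsets[b]) for a, b in COMPARISON_PAIRS
    ]
    depth_summaries = {
        s: depth_summary(cs) for s, cs in callsets.items() if len(cs) > 0
    }
    cohens = {}
    for i, a in enumerate(SCENARIOS):
        for b in SCENARIOS[i + 1 :]:
            if len(callsets[a]) >= 2 and len(callsets[b]) >= 2:
                cohens[(a, b)] = cohens_d_qual(callsets[a], callsets[b])
    curves = {
        ref: aaf_sharing_curve(callsets[ref], callsets["iii"])
        for ref in CURVE_REFERENCES
        if len(callsets[ref]) > 0
    }
    partition = identify_fixed_variants(filtered["iii"])
    detection = _detection_table(truth, filtered)

    bundle = ExperimentBundle(
        config=config,
        filter_config=filter_config,
        samples=samples,
        pileups=pileups,
        truth=truth,
        callsets=callsets,
        filtered=filtered,
        reports=reports,
        comparisons=comparisons,
        depth_summaries=depth_summaries,
        cohens_d=cohens,
        aaf_curves=curves,
        partition=partition,
        detection=detection,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: ExperimentBundle, out_dir: str | Path) -> None:
    """Write VCFs and TSV/JSON summaries of a finished experiment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_truth(bundle.truth, out / "truth.tsv")
    for scenario, cs in bundle.callsets.items():
        write_vcf(cs, out / f"{scenario}.vcf")
        write_vcf(bundle.filtered[scenario], out / f"{scenario}.filtered.vcf")

    pd.DataFrame([r.as_row() for r in bundle.reports.values()]).to_csv(
        out / "filter_reports.tsv", sep="\t", index=False
    )
    pcts, mean, sd = pass_rate_summary(list(bundle.reports.values()))
    pd.DataFrame(
        [
            {
                "label_a": c.label_a,
                "label_b": c.label_b,
                "n_unique_a": c.n_unique_a,
                "n_shared": c.n_shared,
                "n_unique_b": c.n_unique_b,
                "total": c.total,
                "pct_unique_a": c.pct_unique_a,
                "pct_shared": c.pct_shared,
                "pct_unique_b": c.pct_unique_b,
            }
            for c in bundle.comparisons
        ]
    ).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"scenario": s, **asdict(d)} for s, d in bundle.depth_summaries.items()]
    ).to_csv(out / "depth_summaries.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"scenario_a": a, "scenario_b": b, "cohens_d": d} for (a, b), d in bundle.cohens_d.items()]
    ).to_csv(out / "cohens_d.tsv", sep="\t", index=False)
    for ref, curve in bundle.aaf_curves.items():
        pd.DataFrame(
            {
                "bin_low": curve.bin_edges[:-1],
                "bin_high": curve.bin_edges[1:],
                "n": curve.n_variants,
                "pct_shared": curve.pct_shared,
            }
        ).to_csv(out / f"aaf_curve_{ref}_vs_iii.tsv", sep="\t", index=False)
    bundle.detection.to_csv(out / "detection.tsv", sep="\t", index=False)

    summary = {
        "package_version": __version__,
        "seed": bundle.config.seed,
        "n_sites": bundle.config.n_sites,
        "pass_pct_per_scenario": {s: r.pct_pass for s, r in bundle.reports.items()},
        "pass_pct_mean": mean,
        "pass_pct_sd": sd,
        "mean_shared_pct": bundle.mean_shared_pct,
        "partition": {
            "unique_low": bundle.partition.n_unique_low,
            "unique_high": bundle.partition.n_unique_high,
            "shared": bundle.partition.n_shared,
            "total": bundle.partition.total,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
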