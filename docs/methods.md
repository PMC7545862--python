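# Methods

## The question the package operationalizes

Given RNA-seq from a cohort of 12 animals in two divergent phenotype
groups (low/high residual feed intake, RFI) sampled in two tissues
(liver, muscle), SNP calling can proceed from three layouts of the same
reads: (i) every sample its own genotype column under multi-sample
joint calling, (ii) reads merged per (group, tissue) into four pooled
pseudo-samples, or (iii) reads merged per group across tissues into
two. The layouts differ in per-variant depth and in which variants
survive calling and filtering. `mergecall` reproduces the comparison
end to end on synthetic data with known truth, so that the mechanisms
behind the differences — allele dilution in pools, quality-score
inflation across many genotype columns, depth-threshold rescue by
pooling — can be demonstrated and regression-tested rather than argued
from a single large dataset.

## Synthetic cohort generator

The generator emulates the study design at the pileup level: per sample
and site it draws a read depth and an alternative-read count; no reads,
alignments or base qualities are simulated.

* **Design.** 2 groups × 2 tissues × `n_per_group_per_tissue` (default
  6) samples. Genotypes are animal-level: an animal's liver and muscle
  samples share its dosage.
* **Coverage.** Site depth is Poisson with mean
  `mean_depth_liver × gene_factor × (muscle_depth_ratio if muscle)`.
  `mean_depth_liver` defaults to 10 reads/site — low enough that the
  DP ≥ 10 site filter bites for individual tissues, which is the regime
  the comparison is about. `muscle_depth_ratio` defaults to 2.3,
  reflecting the roughly 2.3× higher uniquely-mapped read yield of the
  muscle libraries in the motivating dataset. The per-gene factor is
  log-normal with log-scale SD `expression_dispersion` (default 0.5):
  a moderate spread that leaves most sites callable in a 1000-site
  cohort. Real RNA-seq coverage is far more dispersed (per-variant
  depth distributions with medians orders of magnitude below their
  means); consequences are under Limitations.
* **Variant classes.** Each site belongs to one truth class:
  `FIXED_LOW`/`FIXED_HIGH` (dosage 2 in every animal of one group,
  0 in the other — the strongest reading of "fixed within a group"),
  `SHARED_POLY` (per-animal Hardy–Weinberg dosage with a per-site
  allele frequency uniform on [0.2, 0.8], giving the mid-frequency
  variants that dominate real call sets), `RARE_SINGLETON` (one animal
  heterozygous — the class pooling dilutes), and `INVARIANT` (alt
  reads arise only from error). Default proportions
  0.05/0.05/0.55/0.15/0.20 encode a call set dominated by shared
  polymorphism with a minority of group-specific and rare variation;
  no quantitative class distribution is published for the real data,
  so these are stated assumptions, configurable per run.
* **Class allocation** is deterministic largest-remainder over
  `n_sites` (random placement, exact counts), so tests can assert
  counts exactly rather than within multinomial noise.
* **Reads.** `alt_count ~ Binomial(depth, p)` with
  `p = (dosage/2)(1−ε) + (1−dosage/2)ε`; `error_rate` ε defaults to
  0.01/read, a typical post-trimming substitution-error scale.
* **Context flags.** Gap and INDEL proximity are boolean site flags
  (default 5% of sites each) rather than literal alignments — the
  filter cascade consumes only the predicate. Sites are spaced 10 bp
  apart on one synthetic chromosome so flags stay independent of
  placement.
* Zero-depth cells are retained; the caller treats them as
  uninformative rather than dropping them.

What the generator does **not** emulate: read-level artifacts (mapping
bias, splice junctions, duplicates), base-quality variation,
expression differences between the phenotype groups, linkage between
sites, and multi-allelic sites. Passing tests therefore demonstrate the
pooling/calling/filtering mechanics, not the biology-dependent absolute
counts of any real dataset.

## Pooling

Pools sum member read counts exactly (reads are conserved) and OR the
proximity flags. Real merged BAM files are slightly non-additive
because quality filtering is re-applied after merging; the idealized
additive merge is deliberate — it gives deterministic, testable
semantics — and is the one place the package's depth arithmetic departs
from what a re-run of the original tools would produce.

## Joint caller

Diploid genotype dosages are scored per column with the binomial
likelihood above, a flat prior (1/3 each), and posteriors normalized in
log space (`scipy.special.logsumexp`); site
`QUAL = −10 Σ log10 P(g=0|data)` over informative columns, capped at
10 000. Emission requires QUAL ≥ 3.0103 (any-variant posterior > 0.5)
and ≥ 1 alternative read. Numerical choices:

* All likelihood work is in log space; a linear-space brute-force
  evaluation at depth ≤ 12 serves as the test oracle (agreement to
  1e-9 relative).
* Zero-depth columns contribute factor 1 to QUAL and genotype `./.` —
  no data neither creates nor destroys site evidence.
* Pools of many animals are still scored as diploid. This is exactly
  what a joint caller does to a merged file and is the mechanism behind
  dilution: one het carrier among six animals gives a pooled alt
  fraction ≈ 1/12, which the diploid model explains better as hom-ref
  plus error than as a het, so the site is not emitted.
* The flat prior (no allele-frequency prior across columns) is the
  simplest model exhibiting both dilution and QUAL inflation; it is a
  documented divergence from production callers, whose QUAL magnitudes
  this module does not attempt to reproduce.
* Ties in `argmax` posterior resolve to the lower dosage (numpy
  first-maximum), biasing toward the reference in degenerate cases.

## Filter cascade

Six conjunctive rules in fixed order: DP ≥ 10, total alt reads ≥ 2,
no gap flag, QUAL ≥ 30, no INDEL flag, site AAF ≥ 0.20. The order only
affects per-rule removal attribution; survivors are order-invariant.
The filter AAF is read-based (total alt reads / total reads), which is
computable for pooled single-genotype files; the sharing-curve AAF is
genotype-based (alt dosage / 2 × called genotypes). These deliberately
differ — the 20% "population frequency" rule is ambiguous between the
two readings, and the read-based form is the one that degrades
gracefully for pools. Percentages are rounded half-away-from-zero to
two decimals; a pass rate over an empty set is defined as 0.00 rather
than an error.

## Comparison statistics

* Variant identity is the full (chrom, pos, ref, alt) tuple: the same
  position with a different alternative allele is a different variant
  (same-position different-allele SNPs across groups are a real
  phenomenon the contrast must preserve).
* Depth summaries use linear-interpolation quantiles and sample SD
  (n−1), SD = 0 for n = 1 by convention.
* Cohen's d on QUAL uses the unequal-variance (Welch-style)
  denominator `sqrt((s_a² + s_b²)/2)` and reports the magnitude to
  three decimals.
* AAF-sharing curves bin a reference call set's variants by
  genotype-based AAF (default bin width 0.1; the last bin is closed at
  1.0) and report the percentage of each bin found in the other set.
  Records whose genotypes are all missing are skipped with a warning.

## Group contrast and enrichment

A variant is "present" in a group when the group's genotype carries at
least one alternative allele; hom-ref and missing both count as absent.
This yields the three-way unique-low/shared/unique-high partition.
Variants not annotated in the impact table are excluded from
impact-filtered sets (the downstream analysis proceeds only on
annotated variants); gene assignment is strand-agnostic strict interval
containment with no flanking window, a simplification relative to
consequence predictors that annotate up/downstream variants. Enrichment
is the hypergeometric upper tail per term with both Bonferroni
correction and Benjamini–Hochberg q-values; the significance gate is
FDR < 0.05 to match how such results are usually reported, and the
background defaults to the union of all term gene sets when not given.

## Experiment driver

Seven scenarios are produced per run: `i_liver`, `i_muscle`,
`ii_liver`, `ii_muscle`, `iii`, plus combined-tissue `i_both` and
`ii_both` formed as key-unions of the per-tissue call sets (the first
set's record is kept on overlap; how the original combined rows were
formed is not documented, so the union is a stated assumption).
Sensitivity is scored per truth class as detected-and-filtered /
truth-class size; for invariant sites the false-site rate
(1 − specificity) is reported instead.

## Problem sizes and determinism

The default cohort is 1000 sites × 24 samples (12 animals × 2
tissues), which runs the full seven-scenario experiment in a few
seconds; tests and the acceptance script use this size, with smaller
cohorts (30–200 sites) for shape and round-trip checks. All randomness
flows from a single `numpy.random.default_rng(seed)`; identical config
and seed reproduce pileups and truth byte-for-byte.

## Known limitations

* Mean per-variant depth differences between approaches i and ii
  within a tissue are a sub-percent effect driven by a handful of
  low-depth error sites unique to non-merged calling; at 1000 sites
  this ordering is near the sampling-noise floor, unlike the robust
  orderings involving approach iii.
* The rare-singleton class never survives the 20% AAF filter in any
  approach (a singleton is ~4% of alleles in a 12-animal cohort), so
  post-filter sensitivity contrasts are only informative for the fixed
  and shared classes; dilution is visible pre-filter.
* QUAL magnitudes are model-specific and not comparable to production
  callers; only their orderings and threshold crossings are meaningful.
* Multi-allelic sites are supported on VCF input (split per alternative
  allele) but never generated or called internally.
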