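# mergecall

Compare RNA-seq sample-merging strategies for SNP detection.

When SNPs are called from RNA-seq of a cohort split into divergent
phenotype groups (here: low vs high residual feed intake, two tissues,
six animals per group), the analyst must decide how to combine samples
before calling: keep every sample as its own genotype column
(**approach i**, non-merged joint calling), merge reads by group within
each tissue (**approach ii**), or merge by group across tissues
(**approach iii**). The choice trades per-variant read depth against
the ability to see variants carried by few animals: pooling raises
depth past filter thresholds, but *dilutes* low-frequency variants into
the sequencing-error regime, while many genotype columns *inflate* the
site quality score. `mergecall` makes those trade-offs reproducible at
desk scale: a synthetic pileup cohort with known truth, a simplified
joint caller that exhibits both mechanisms, the standard six-rule
filter cascade, and the comparison statistics used to pick an approach
— variant-set partitions, depth summaries, Cohen's d on QUAL,
allele-frequency sharing curves — plus fixed-within-group SNP
identification and gene-set enrichment downstream.

## Model

Per genotype column (a sample or a pool) with read counts
(ref, alt) = (n−k, k), the caller scores diploid dosages g ∈ {0, 1, 2}
with a binomial read model,

    L(g) = C(n, k) p_g^k (1 − p_g)^(n−k),
    p_g  = (g/2)(1 − ε) + (1 − g/2) ε,

where ε is the per-read error rate (default 0.01). With a flat prior,
site quality is the Phred-scaled probability that no genotype carries
the alternative allele,

    QUAL = −10 · Σ_s log10 P(g_s = 0 | data_s),

summed over genotypes with data and capped at 10 000. A site is emitted
when QUAL ≥ 3.0103 (posterior of "any variant" > 0.5) and at least one
alternative read was seen. Records then pass a conjunctive filter
cascade — DP ≥ 10, alt reads ≥ 2, not near a gap, QUAL ≥ 30, not near
an INDEL, read-based alternative allele frequency ≥ 0.20 — applied in
that order for removal attribution. Full details, including what the
generator does and does not emulate, are in `docs/methods.md`.

## Worked example

```python
import mergecall as mc

bundle = mc.run_experiment(mc.CohortConfig(seed=7))

for scenario, rep in bundle.reports.items():
    print(f"{scenario:9s} {rep.n_before:5d} -> {rep.n_after:5d}  ({rep.pct_pass:.2f}% pass)")
for c in bundle.comparisons:
    print(f"{c.label_a} vs {c.label_b}: shared {c.pct_shared:.2f}%")
p = bundle.partition
print(f"fixed-SNP partition: {p.n_unique_low} unique-low / {p.n_shared} shared / {p.n_unique_high} unique-high")
```

prints

```
i_liver     838 ->   552  (65.87% pass)
i_muscle    806 ->   555  (68.86% pass)
i_both      845 ->   552  (65.33% pass)
ii_liver    656 ->   552  (84.15% pass)
ii_muscle   650 ->   555  (85.38% pass)
ii_both     665 ->   553  (83.16% pass)
iii         650 ->   557  (85.69% pass)
i_liver vs ii_liver: shared 78.28%
i_muscle vs ii_muscle: shared 80.65%
i_both vs iii: shared 76.92%
ii_both vs iii: shared 97.74%
fixed-SNP partition: 56 unique-low / 448 shared / 53 unique-high
```

The non-merged scenarios start with more raw calls (838 vs 650 for
liver) because they keep rare singletons and error-driven sites that
pooling dilutes away; almost all of that surplus is then removed by the
filter cascade, which is why their pass percentage is lower. The two
merged approaches agree with each other far more (97.74% shared) than
either agrees with non-merged calling, and the fully merged approach
has the highest mean per-variant depth (439.7 reads vs 131–306 for the
others, `bundle.depth_summaries`). The final partition splits the
filtered by-group call set into SNPs carried only by the low-RFI group,
only by the high-RFI group, or both.

The same pipeline is scriptable from the shell via the `mergecall`
umbrella command (`simulate`, `call`, `filter`, `compare`, `contrast`,
`enrich`, `run-experiment`); every subcommand writes a JSON
run-manifest next to its outputs.

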