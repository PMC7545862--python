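"""Set partitions, depth summaries, Cohen's d, AAF-sharing curves."""

import math
from fractions import Fraction

import numpy as np
import pytest

from mergecall import (
    CallSet,
    VariantKey,
    VariantRecord,
    aaf_sharing_curve,
    cohens_d_qual,
    depth_summary,
    mean_shared_percentage,
    partition_variants,
)
from mergecall.caller import GenotypeCall
from mergecall.compare import genotype_aaf


def key(i):
    return VariantKey("1", i, "C", "G")


def qual_callset(quals, label="q"):
    records = [
        VariantRecord("1", 10 * i, "C", "G", q, 20, False, False,
                      {"g": GenotypeCall("0/1", (10, 10), 20)})
        for i, q in enumerate(quals, 1)
    ]
    return CallSet(label=label, genotype_ids=["g"], records=records)


class TestPartition:
    def test_identical_sets_fully_shared(self):
        res = partition_variants({key(i) for i in range(5)}, {key(i) for i in range(5)})
        assert (res.n_unique_a, res.n_shared, res.n_unique_b) == (0, 5, 0)
        assert res.pct_shared == 100.00

    def test_disjoint_singletons(self):
        res = partition_variants({key(1)}, {key(2)})
        assert (res.n_unique_a, res.n_shared, res.n_unique_b) == (1, 0, 1)
        assert (res.pct_unique_a, res.pct_shared, res.pct_unique_b) == (50.00, 0.00, 50.00)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            partition_variants(set(), set())

    def test_percentages_sum_to_hundred(self):
        res = partition_variants({key(i) for i in range(7)}, {key(i) for i in range(3, 12)})
        assert res.pct_unique_a + res.pct_shared + res.pct_unique_b == pytest.approx(100.0, abs=0.02)

    def test_symmetry(self):
        a = {key(i) for i in range(6)}
        b = {key(i) for i in range(4, 9)}
        ab, ba = partition_variants(a, b), partition_variants(b, a)
        assert (ab.n_unique_a, ab.n_shared, ab.n_unique_b) == (ba.n_unique_b, ba.n_shared, ba.n_unique_a)


class TestMeanShared:
    def test_single_result_is_itself(self):
        res = partition_variants({key(1), key(2)}, {key(2)})
        assert mean_shared_percentage([res]) == res.pct_shared

    def test_mean_of_extremes(self):
        full = partition_variants({key(1)}, {key(1)})
        none = partition_variants({key(1)}, {key(2)})
        assert mean_shared_percentage([full, none]) == 50.00


class TestDepthSummary:
    def test_three_point_summary(self):
        cs = qual_callset([50, 50, 50])
        for r, d in zip(cs.records, (2, 4, 6)):
            r.dp = d
        s = depth_summary(cs)
        assert (s.minimum, s.q1, s.median, s.q3, s.maximum) == (2, 3, 4, 5, 6)
        assert (s.mean, s.sd) == (4, 2)

    def test_single_record(self):
        cs = qual_callset([50])
        cs.records[0].dp = 7
        s = depth_summary(cs)
        assert (s.minimum, s.median, s.maximum, s.sd) == (7, 7, 7, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            depth_summary(CallSet("empty", ["g"], []))

    def test_quantiles_are_ordered(self, default_bundle):
        for s in default_bundle.depth_summaries.values():
            assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum


class TestCohensD:
    def test_identical_distributions(self):
        assert cohens_d_qual(qual_callset([1, 2, 3]), qual_callset([1, 2, 3])) == 0.0

    def test_hand_computed_example(self):
        assert cohens_d_qual(qual_callset([1, 2, 3]), qual_callset([4, 5, 6])) == 3.000

    def test_scale_invariance(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 8.0, 9.0]
        d1 = cohens_d_qual(qual_callset(a), qual_callset(b))
        d2 = cohens_d_qual(qual_callset([7 * x for x in a]), qual_callset([7 * x for x in b]))
        assert d1 == pytest.approx(d2, abs=1e-3)

    def test_matches_exact_rational_arithmetic(self):
        qa, qb = [3, 7, 11, 4], [10, 2, 8, 8, 9]
        def mean(v):
            return Fraction(sum(v), len(v))
        def var(v):
            m = mean(v)
            return sum((Fraction(x) - m) ** 2 for x in v) / (len(v) - 1)
        exact = abs(mean(qa) - mean(qb)) / math.sqrt(float((var(qa) + var(qb)) / 2))
        got = cohens_d_qual(qual_callset(qa), qual_callset(qb))
        assert got == pytest.approx(float(exact), abs=5e-4)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_qual(qual_callset([1]), qual_callset([1, 2]))


def aaf_callset(aafs, label="ref"):
    """One biallelic record per requested AAF, using 5 diploid genotypes."""
    records = []
    for i, aaf in enumerate(aafs, 1):
        n_alt = round(aaf * 10)
        gts = ["1/1"] * (n_alt // 2) + ["0/1"] * (n_alt % 2)
        gts += ["0/0"] * (5 - len(gts))
        records.append(
            VariantRecord("1", 10 * i, "C", "G", 50.0, 50, False, False,
                          {f"s{j}": GenotypeCall(g, (5, 5), 10) for j, g in enumerate(gts)})
        )
    return CallSet(label=label, genotype_ids=[f"s{j}" for j in range(5)], records=records)


class TestAAFSharingCurve:
    def test_genotype_based_aaf(self):
        cs = aaf_callset([0.3])
        assert genotype_aaf(cs.records[0]) == pytest.approx(0.3)

    def test_missing_genotypes_excluded_from_denominator(self):
        cs = aaf_callset([0.2])
        rec = cs.records[0]
        rec.genotypes["s4"] = GenotypeCall("./.", (0, 0), 0)
        assert genotype_aaf(rec) == pytest.approx(2 / 8)

    def test_superset_other_gives_full_sharing(self):
        ref = aaf_callset([0.1, 0.5, 0.9])
        curve = aaf_sharing_curve(ref, ref.keys(), bin_width=0.5)
        assert all(p == 100.0 for p, n in zip(curve.pct_shared, curve.n_variants) if n)

    def test_disjoint_other_gives_zero_sharing(self):
        ref = aaf_callset([0.1, 0.9])
        curve = aaf_sharing_curve(ref, {VariantKey("9", 1, "A", "T")}, bin_width=0.5)
        assert all(p == 0.0 for p, n in zip(curve.pct_shared, curve.n_variants) if n)

    def test_sharing_rises_with_frequency(self):
        ref = aaf_callset([0.1, 0.1, 0.9, 0.9])
        high_keys = {VariantKey(*r.key) for r in ref.records[2:]}
        curve = aaf_sharing_curve(ref, high_keys, bin_width=0.5)
        assert curve.pct_shared == (0.0, 100.0)
        assert curve.n_variants == (2, 2)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError, match="bin_width"):
            aaf_sharing_curve(aaf_callset([0.5]), set(), bin_width=0.3)

    def test_low_frequency_variants_shared_less_on_default_cohort(self, default_bundle):
        """Non-merged vs fully merged: sharing is higher for common variants."""
        curve = default_bundle.aaf_curves["i_both"]
        edges = np.array(curve.bin_edges)
        n = np.array(curve.n_variants, dtype=float)
        shared = np.array([p / 100 * c if c else 0.0 for p, c in zip(curve.pct_shared, n)])
        low = edges[1:] <= 0.2
        high = edges[:-1] >= 0.7
        pct_low = shared[low].sum() / n[low].sum() * 100
        pct_high = shared[high].sum() / n[high].sum() * 100
        assert pct_high > pct_low
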