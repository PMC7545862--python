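"""Synthetic cohort generator: truth structure, depth model, round trips."""

import numpy as np
import pandas as pd
import pytest

from mergecall import CohortConfig, Group, Tissue, VariantClass, read_truth, simulate_cohort, write_truth
from mergecall.cohort import CohortConfigError, TruthParseError, largest_remainder_allocation


def _only(cls):
    return {c: (1.0 if c is cls else 0.0) for c in VariantClass}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_sites", 0),
            ("n_per_group_per_tissue", -1),
            ("error_rate", 1.5),
            ("gap_fraction", -0.1),
            ("mean_depth_liver", 0.0),
        ],
    )
    def test_invalid_field_is_named(self, field, value):
        with pytest.raises(CohortConfigError, match=field):
            CohortConfig(**{field: value}).validate()

    def test_proportions_must_sum_to_one(self):
        props = _only(VariantClass.INVARIANT)
        props[VariantClass.SHARED_POLY] = 0.5
        with pytest.raises(CohortConfigError, match="class_proportions"):
            CohortConfig(class_proportions=props).validate()


class TestLargestRemainder:
    def test_exact_default_split(self):
        assert largest_remainder_allocation([0.05, 0.05, 0.55, 0.15, 0.20], 1000) == [
            50,
            50,
            550,
            150,
            200,
        ]

    @pytest.mark.parametrize("total", [1, 7, 99, 1234])
    def test_counts_always_sum_to_total(self, total):
        counts = largest_remainder_allocation([0.31, 0.333, 0.357], total)
        assert sum(counts) == total


class TestSimulation:
    def test_truth_class_counts_are_deterministic(self):
        _, _, truth = simulate_cohort(CohortConfig(n_sites=1000, seed=3))
        counts = truth["class"].value_counts()
        assert counts["SHARED_POLY"] == 550
        assert counts["FIXED_LOW"] == counts["FIXED_HIGH"] == 50
        assert counts["RARE_SINGLETON"] == 150
        assert counts["INVARIANT"] == 200

    def test_invariant_only_noise_free_has_no_alt_reads(self):
        cfg = CohortConfig(
            n_sites=50, error_rate=0.0, class_proportions=_only(VariantClass.INVARIANT), seed=1
        )
        _, pileups, _ = simulate_cohort(cfg)
        assert (pileups["alt_count"] == 0).all()

    def test_fixed_low_noise_free_site_is_all_alt_in_low_group(self):
        cfg = CohortConfig(
            n_sites=1,
            error_rate=0.0,
            mean_depth_liver=50,
            expression_dispersion=0.0,
            class_proportions=_only(VariantClass.FIXED_LOW),
            seed=2,
        )
        samples, pileups, _ = simulate_cohort(cfg)
        group = {s.sample_id: s.group for s in samples}
        for row in pileups.itertuples(index=False):
            if group[row.sample_id] is Group.LOW_RFI:
                assert row.ref_count == 0  # dosage 2, no error: every read is alt
            else:
                assert row.alt_count == 0

    def test_muscle_to_liver_depth_ratio(self):
        # Monte-Carlo check of the tissue coverage ratio at 1000 sites x 6
        # samples per cell; tolerance reflects Poisson/binomial sampling error.
        cfg = CohortConfig(n_sites=1000, seed=1)
        samples, pileups, _ = simulate_cohort(cfg)
        tissue = {s.sample_id: s.tissue for s in samples}
        depth = pileups["ref_count"] + pileups["alt_count"]
        by_tissue = depth.groupby(pileups["sample_id"].map(tissue)).mean()
        ratio = by_tissue[Tissue.MUSCLE] / by_tissue[Tissue.LIVER]
        assert 2.3 * 0.85 <= ratio <= 2.3 * 1.15

    def test_reproducible_and_seed_sensitive(self):
        cfg = CohortConfig(n_sites=100, seed=7)
        _, p1, t1 = simulate_cohort(cfg)
        _, p2, t2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1, t2)
        _, p3, _ = simulate_cohort(cfg.with_(seed=8))
        assert not p1.equals(p3)

    def test_noise_free_alt_reads_only_in_carriers(self):
        cfg = CohortConfig(n_sites=200, error_rate=0.0, seed=5)
        samples, pileups, truth = simulate_cohort(cfg)
        dosage = truth.set_index("pos")[[s.sample_id for s in samples]]
        merged = pileups.merge(
            dosage.stack().rename("dosage"),
            left_on=["pos", "sample_id"],
            right_index=True,
        )
        with_alt = merged[merged["alt_count"] > 0]
        assert (with_alt["dosage"] > 0).all()

    def test_singleton_sites_have_exactly_one_carrier_animal(self):
        cfg = CohortConfig(n_sites=200, seed=11)
        samples, _, truth = simulate_cohort(cfg)
        animals = {s.animal_id for s in samples}
        singles = truth[truth["class"] == "RARE_SINGLETON"]
        for _, row in singles.iterrows():
            carriers = {
                s.animal_id for s in samples if row[s.sample_id] > 0
            }
            assert len(carriers) == 1, f"site {row.pos}: carriers {carriers}"
        assert len(animals) == 12


class TestTruthRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        _, _, truth = simulate_cohort(CohortConfig(n_sites=30, seed=4))
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        back = read_truth(path)
        pd.testing.assert_frame_equal(truth, back)

    def test_shape(self, tmp_path):
        _, _, truth = simulate_cohort(CohortConfig(n_sites=3, seed=4))
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4  # header + 3 sites
        assert len(lines[0].split("\t")) == 8 + 24  # fixed cols + dosage per sample

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_truth(pd.DataFrame(), tmp_path / "x.tsv")

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tref\talt\tclass\tgene_id\tnear_gap\tnear_indel\ts1\n"
                        "1\toops\tA\tC\tINVARIANT\tg1\t0\t0\t0\n")
        with pytest.raises(TruthParseError, match="line 2"):
            read_truth(path)
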