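import numpy as np
import pandas as pd
import pytest

from gsgwas.genotype_io import (EmptyResultError, FormatError, filter_lines,
                                filter_markers, impute_missing, read_genotypes,
                                subset_markers, write_dosage_tsv)

from conftest import make_genotypes


class TestReaders:
    def test_dosage_tsv_with_missing_cell(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("line_id\tm1\tm2\nA\t0\t2\nB\t1\tNA\nC\t2\t0\n")
        g = read_genotypes(path, "dosage_tsv")
        assert g.line_ids == ["A", "B", "C"]
        assert g.missing_mask.sum() == 1
        assert np.isnan(g.dosage[1, 1])
        np.testing.assert_array_equal(g.dosage[:, 0], [0, 1, 2])

    def test_dosage_tsv_rejects_fractional_values(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("line_id\tm1\nA\t0.5\n")
        with pytest.raises(FormatError):
            read_genotypes(path, "dosage_tsv")

    def test_vcf_gt_coding(self, vcf_file):
        path = vcf_file(["1\t100\ts1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1"])
        g = read_genotypes(path, "vcf")
        np.testing.assert_array_equal(g.dosage[:, 0], [0, 1, 2])
        assert g.markers.loc[0, "allele_alt"] == "G"
        assert g.markers.loc[0, "position_bp"] == 100

    def test_vcf_skips_triallelic_records(self, vcf_file):
        recs = [f"1\t{100 * (i + 1)}\ts{i}\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1"
                for i in range(4)]
        recs.insert(2, "1\t250\tbad\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2")
        g = read_genotypes(vcf_file(recs), "vcf")
        assert g.n_markers == 4
        assert "1 non-biallelic records skipped" in g.provenance[0]

    def test_vcf_missing_genotype(self, vcf_file):
        path = vcf_file(["1\t100\ts1\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t1/1"])
        g = read_genotypes(path, "vcf")
        assert np.isnan(g.dosage[0, 0])

    def test_hapmap_pair_and_iupac_calls(self, hapmap_file):
        path = hapmap_file([
            "m1\tA/G\t1\t100\t+\tNA\tNA\tNA\tNA\tNA\tNA\tAA\tAG\tGG",
            "m2\tC/T\t1\t200\t+\tNA\tNA\tNA\tNA\tNA\tNA\tC\tY\tNN",
        ])
        g = read_genotypes(path, "hapmap")
        np.testing.assert_array_equal(g.dosage[:, 0], [0, 1, 2])
        assert g.dosage[0, 1] == 0 and g.dosage[1, 1] == 1
        assert np.isnan(g.dosage[2, 1])

    def test_hapmap_bad_call_raises(self, hapmap_file):
        path = hapmap_file(["m1\tA/G\t1\t100\t+\tNA\tNA\tNA\tNA\tNA\tNA\tAA\tAC\tGG"])
        with pytest.raises(FormatError):
            read_genotypes(path, "hapmap")

    def test_roundtrip_dosage_tsv(self, tmp_path):
        g = make_genotypes([[0, 1], [2, np.nan], [1, 0]])
        write_dosage_tsv(g, tmp_path / "out.tsv")
        g2 = read_genotypes(tmp_path / "out.tsv", "dosage_tsv")
        np.testing.assert_array_equal(np.isnan(g.dosage), np.isnan(g2.dosage))
        np.testing.assert_allclose(np.nan_to_num(g.dosage), np.nan_to_num(g2.dosage))
        assert (tmp_path / "out.tsv.provenance.json").exists()


class TestFilters:
    def test_call_rate_filter(self):
        # 2/4 observed < 0.75 -> removed; the complete marker stays
        g = make_genotypes([[0, 0], [np.nan, 1], [np.nan, 2], [2, 1]])
        out = filter_markers(g, min_call_rate=0.75)
        assert out.markers["marker_id"].tolist() == ["m2"]

    def test_monomorphic_removed(self):
        g = make_genotypes([[0, 0], [0, 1], [0, 2], [0, 1]])
        out = filter_markers(g, min_call_rate=0.0)
        assert out.markers["marker_id"].tolist() == ["m2"]

    def test_maf_boundary_retained(self):
        # dosages (0,0,0,2): alt freq 2/8 = 0.25 >= 0.05 -> retained
        g = make_genotypes([[0], [0], [0], [2]])
        out = filter_markers(g, min_call_rate=0.0, min_maf=0.05)
        assert out.n_markers == 1

    def test_all_removed_raises_with_attrition(self):
        g = make_genotypes([[0], [0], [0], [0]])
        with pytest.raises(EmptyResultError, match="monomorphic"):
            filter_markers(g)

    def test_line_missingness_thresholds(self):
        fracs = [0.0, 0.2, 0.61, 0.6, 1.0]
        dosage = np.ones((5, 100))
        for i, f in enumerate(fracs):
            dosage[i, : int(round(f * 100))] = np.nan
        g = make_genotypes(dosage)
        out = filter_lines(g, max_missing=0.6)
        assert out.line_ids == ["L1", "L2", "L4"]

    def test_line_with_70pct_missing_dropped(self):
        dosage = np.ones((3, 10))
        dosage[0, :7] = np.nan
        out = filter_lines(make_genotypes(dosage), max_missing=0.6)
        assert "L1" not in out.line_ids and "L2" in out.line_ids

    def test_filtering_idempotent(self, sim_population):
        g = sim_population["g"]
        rng = np.random.default_rng(0)
        dosage = g.dosage.copy()
        dosage[rng.random(dosage.shape) < 0.15] = np.nan
        g = make_genotypes(dosage)
        once = filter_markers(filter_lines(g), min_maf=0.05)
        twice = filter_markers(filter_lines(once), min_maf=0.05)
        assert once.markers["marker_id"].tolist() == twice.markers["marker_id"].tolist()
        assert once.line_ids == twice.line_ids

    def test_attrition_counts_sum(self):
        rng = np.random.default_rng(1)
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(20, 200),
                            p=[0.45, 0.05, 0.3, 0.2])
        g = make_genotypes(dosage)
        out = filter_markers(g, min_call_rate=0.8, min_maf=0.1)
        counts = [int(s) for s in out.provenance[-1].replace(";", "").split()
                  if s.isdigit()]
        removed_cr, removed_maf, removed_mono, retained = counts
        assert removed_cr + removed_maf + removed_mono + retained == g.n_markers
        assert retained == out.n_markers


class TestImputation:
    def test_marker_mean_fill(self):
        g = make_genotypes([[0], [2], [np.nan]])
        out = impute_missing(g)
        assert out.dosage[2, 0] == pytest.approx(1.0)

    def test_no_missing_identity(self):
        g = make_genotypes([[0, 1], [2, 1]])
        assert impute_missing(g) is g

    def test_constant_observed(self):
        g = make_genotypes([[2], [np.nan], [np.nan], [2]])
        np.testing.assert_allclose(impute_missing(g).dosage[:, 0], 2.0)

    def test_preserves_observed_means(self):
        rng = np.random.default_rng(2)
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(30, 50),
                            p=[0.4, 0.1, 0.3, 0.2])
        dosage[0] = 1.0  # ensure every marker observed at least once
        g = make_genotypes(dosage)
        out = impute_missing(g)
        # filling with the observed mean leaves every column mean unchanged
        np.testing.assert_allclose(out.dosage.mean(axis=0),
                                   np.nanmean(g.dosage, axis=0))
        # observed entries untouched
        mask = ~np.isnan(g.dosage)
        np.testing.assert_array_equal(out.dosage[mask], g.dosage[mask])

    def test_zero_observed_calls_rejected(self):
        g = make_genotypes([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="filter_markers"):
            impute_missing(g)


class TestSubsetting:
    def test_identity_subset(self):
        g = make_genotypes(np.zeros((2, 5)) + [[0, 1, 2, 0, 1], [2, 1, 0, 2, 1]])
        for mode in ("random", "distributed"):
            out = subset_markers(g, 5, mode, seed=0)
            assert out.markers["marker_id"].tolist() == g.markers["marker_id"].tolist()

    def test_random_deterministic_under_seed(self, sim_population):
        g = sim_population["g"]
        a = subset_markers(g, 100, "random", seed=7)
        b = subset_markers(g, 100, "random", seed=7)
        assert a.markers["marker_id"].tolist() == b.markers["marker_id"].tolist()

    def test_random_seeds_differ(self, sim_population):
        g = sim_population["g"]
        subsets = {tuple(subset_markers(g, 100, "random", seed=s)
                         .markers["marker_id"]) for s in range(10)}
        assert len(subsets) >= 9

    def test_distributed_bin_centers(self):
        # 10 markers at 1..10 Mb on one chromosome, n=5: bin centers at
        # 1,3,5,7,9 Mb coincide with markers
        pos = np.arange(1, 11) * 1_000_000
        g = make_genotypes(np.arange(20).reshape(2, 10) % 3, positions=pos)
        out = subset_markers(g, 5, "distributed", seed=0)
        got = out.markers["position_bp"].tolist()
        assert got == [1_000_000, 3_000_000, 5_000_000, 7_000_000, 9_000_000]

    def test_distributed_spans_chromosomes(self, sim_population):
        g = sim_population["g"]
        out = subset_markers(g, 50, "distributed", seed=0)
        assert out.n_markers == 50
        assert out.markers["chromosome"].nunique() == g.markers["chromosome"].nunique()

    def test_n_too_large(self, sim_population):
        with pytest.raises(ValueError):
            subset_markers(sim_population["g"], 10 ** 6, "random", seed=0)
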