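import numpy as np
import pandas as pd
import pytest

from gsgwas.cv_engine import (TrainingComposition, adjust_phenotypes, build_folds,
                              multi_environment_sweep, run_cv)
from gsgwas.genotype_io import PhenotypeTable

from conftest import make_genotypes


class TestFolds:
    def test_five_identical_pairs_cluster_together(self):
        rng = np.random.default_rng(0)
        base = rng.choice([0.0, 2.0], size=(5, 40))
        dosage = np.repeat(base, 2, axis=0)  # 5 identical pairs
        g = make_genotypes(dosage)
        folds = build_folds(g, n_folds=2, k_candidates=list(range(2, 10)), seed=0)
        assert folds.k_chosen == 5
        for i in range(5):
            a, b = g.line_ids[2 * i], g.line_ids[2 * i + 1]
            assert folds.fold_of[a] == folds.fold_of[b]

    def test_singleton_clusters_balance_folds(self):
        rng = np.random.default_rng(1)
        g = make_genotypes(rng.choice([0.0, 2.0], size=(30, 80)))
        folds = build_folds(g, n_folds=5, k_candidates=[29], seed=3, refine=False)
        sizes = pd.Series(folds.fold_of).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_deterministic_under_seed(self, sim_population):
        g = sim_population["g"]
        a = build_folds(g, k_candidates=[30, 50], seed=11, refine=False)
        b = build_folds(g, k_candidates=[30, 50], seed=11, refine=False)
        assert a.fold_of == b.fold_of and a.k_chosen == b.k_chosen

    def test_cluster_never_split_across_folds(self, sim_population):
        g = sim_population["g"]
        for seed in range(3):
            folds = build_folds(g, k_candidates=[40], seed=seed, refine=False)
            df = pd.DataFrame({"cluster": pd.Series(folds.cluster_of),
                               "fold": pd.Series(folds.fold_of)})
            assert (df.groupby("cluster")["fold"].nunique() == 1).all()

    def test_families_usually_share_folds(self, sim_population):
        # full sibs share only ~half their genome, so clusters recover
        # families imperfectly — but far above the ~0.8% chance rate of four
        # sibs landing in one of five folds at random
        g, ped = sim_population["g"], sim_population["pedigree"]
        folds = build_folds(g, k_candidates=list(range(10, 101, 10)), seed=0,
                            refine=False)
        df = pd.DataFrame({"fam": pd.Series(ped), "fold": pd.Series(folds.fold_of)})
        frac_intact = (df.groupby("fam")["fold"].nunique() == 1).mean()
        assert frac_intact > 0.3


def pheno_cell(values_by_line, rep_of=None, trait="T", site="S1", year=2012,
               season="dry"):
    rows = []
    for (line, rep), v in values_by_line.items():
        rows.append({"line_id": line, "trait": trait, "value": v, "site": site,
                     "year": year, "season": season, "rep": rep})
    return PhenotypeTable(pd.DataFrame(rows))


class TestAdjustedPhenotypes:
    def test_single_rep_returns_observed(self):
        p = pheno_cell({("A", 1): 3.0, ("B", 1): 5.0})
        adj = adjust_phenotypes(p, ("S1", 2012, "dry"), "T")
        assert adj["A"] == 3.0 and adj["B"] == 5.0

    def test_rep_effect_removed_in_unbalanced_design(self):
        # rep 2 adds +1; line B observed only in rep 2. LS-means put every
        # line on the same rep-averaged scale, so B is not inflated.
        mu = {"A": 1.0, "B": 2.0, "C": 3.0}
        vals = {("A", 1): 1.0, ("A", 2): 2.0, ("C", 1): 3.0, ("C", 2): 4.0,
                ("B", 2): 3.0}
        adj = adjust_phenotypes(pheno_cell(vals), ("S1", 2012, "dry"), "T")
        diffs = adj - pd.Series(mu)
        np.testing.assert_allclose(diffs, diffs.iloc[0], atol=1e-10)

    def test_balanced_rep_effect_exact(self):
        mu = {"A": 1.0, "B": 4.0}
        vals = {("A", 1): 1.0, ("A", 2): 2.0, ("B", 1): 4.0, ("B", 2): 5.0}
        adj = adjust_phenotypes(pheno_cell(vals), ("S1", 2012, "dry"), "T")
        assert adj["B"] - adj["A"] == pytest.approx(mu["B"] - mu["A"])

    def test_absent_line_excluded(self):
        p = pheno_cell({("A", 1): 3.0})
        adj = adjust_phenotypes(p, ("S1", 2012, "dry"), "T")
        assert "B" not in adj.index

    def test_missing_trait_in_cell(self):
        p = pheno_cell({("A", 1): 3.0})
        with pytest.raises(ValueError, match="no records"):
            adjust_phenotypes(p, ("S1", 2012, "dry"), "OTHER")


@pytest.fixture(scope="module")
def cv_setup(sim_population):
    g = sim_population["g"]
    p = sim_population["p"]
    folds = build_folds(g, n_folds=5, k_candidates=[30, 50, 70], seed=2,
                        refine=False)
    comp = TrainingComposition(included=[("S1", 2012, "dry")],
                               validation_cell=("S1", 2012, "dry"))
    return g, p, folds, comp


class TestRunCv:
    def test_partition_and_reproducibility(self, cv_setup):
        g, p, folds, comp = cv_setup
        res = run_cv(g, p, "T", comp, "rrblup", folds, seed=3)
        res2 = run_cv(g, p, "T", comp, "rrblup", folds, seed=3)
        pd.testing.assert_frame_equal(res.folds, res2.folds)
        assert res.mean_accuracy == res2.mean_accuracy
        assert sorted(res.folds["fold"]) == [1, 2, 3, 4, 5]
        assert res.folds["n_test"].sum() == g.n_lines
        assert res.mean_accuracy == pytest.approx(res.folds["accuracy"].mean())

    def test_no_leakage_audit(self, cv_setup):
        g, p, folds, comp = cv_setup
        res = run_cv(g, p, "T", comp, "rrblup_fe_denovo", folds,
                     gwas_source_cell=("S1", 2012, "dry"), seed=3,
                     gwas_mode="p3d")
        assert res.audit["leakage_checked"]
        for f, info in res.audit["folds"].items():
            assert info["train_test_overlap"] == 0
            assert info["gwas_test_overlap"] == 0
        assert set(res.fixed_sets) == {1, 2, 3, 4, 5}

    def test_denovo_beats_noise_free_floor(self, cv_setup, sim_population):
        # the simulated trait carries a 20%-PVE QTL: the de novo fixed-effect
        # model should at least match plain RR-BLUP on average
        g, p, folds, comp = cv_setup
        plain = run_cv(g, p, "T", comp, "rrblup", folds, seed=3)
        denovo = run_cv(g, p, "T", comp, "rrblup_fe_denovo", folds,
                        gwas_source_cell=("S1", 2012, "dry"), seed=3,
                        gwas_mode="p3d")
        assert denovo.mean_accuracy > plain.mean_accuracy - 0.05

    def test_external_gwas_route(self, cv_setup):
        from gsgwas.gwas import run_lmm_gwas
        from gsgwas.kinship import compute_grm
        g, p, folds, comp = cv_setup
        y = adjust_phenotypes(p, ("S1", 2012, "dry"), "T").loc[g.line_ids].to_numpy()
        table = run_lmm_gwas(g, y, compute_grm(g), mode="p3d")
        res = run_cv(g, p, "T", comp, "rrblup_fe_external", folds,
                     external_gwas=table, seed=3)
        assert np.isfinite(res.mean_accuracy)

    def test_random_gebv_accuracy_centered_on_zero(self, cv_setup):
        g, p, folds, comp = cv_setup
        y = adjust_phenotypes(p, ("S1", 2012, "dry"), "T")
        rng = np.random.default_rng(0)
        accs = [np.corrcoef(rng.standard_normal(66), y.iloc[:66])[0, 1]
                for _ in range(50)]
        assert abs(np.mean(accs)) < 0.1

    def test_missing_gwas_cell_rejected(self, cv_setup):
        g, p, folds, comp = cv_setup
        with pytest.raises(ValueError, match="gwas_source_cell"):
            run_cv(g, p, "T", comp, "rrblup_fe_denovo", folds, seed=0)


class TestSweep:
    def test_identical_compositions_identical_rows(self, cv_setup):
        g, p, folds, comp = cv_setup
        comp2 = TrainingComposition(included=list(comp.included),
                                    validation_cell=comp.validation_cell,
                                    name="copy")
        table = multi_environment_sweep(g, p, "T", [comp, comp2], ["rrblup"],
                                        folds, seed=1)
        a = table[table["composition"] == comp.name]["accuracy"].to_numpy()
        b = table[table["composition"] == "copy"]["accuracy"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_validation_cell_auto_added(self, sim_population, cv_setup):
        g, p, folds, _ = cv_setup
        # composition omits the validation cell entirely; CV1 adds it back
        # (minus the validation individuals)
        comp = TrainingComposition(included=[], validation_cell=("S1", 2012, "dry"),
                                   name="empty")
        res = run_cv(g, p, "T", comp, "rrblup", folds, seed=0)
        assert np.isfinite(res.mean_accuracy)
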