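"""Scenario designs, Mantel/Wilcoxon statistics, FV2 composition tuning."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations, permutations

import haplogp as hg
from haplogp.evalstats import (
    bonferroni,
    fv2_composition,
    make_method,
    mantel_test,
    run_scenario1,
    run_scenario_across,
    signed_rank_test,
    tune_min_subgroup,
    wilcoxon_signed_rank,
)

from conftest import dense_map


@pytest.fixture(scope="module")
def scenario_pop(ke_pool):
    pop = hg.sim_dh_population(ke_pool, 50, seed=21)
    qtl = hg.additive_qtl_model(pop.n_snp, 40, seed=22)
    pheno = hg.sim_phenotypes(pop, qtl, 0.7, seed=23)
    return pop, pheno


class TestScenario1:
    def test_record_counts_and_fold_partition(self, scenario_pop):
        pop, pheno = scenario_pop
        rec = run_scenario1(pop, pheno, ["snp"], k=5, iters=2, seed=1)
        assert len(rec) == 10
        assert rec["replicate"].nunique() == 10

    def test_same_seed_reproduces_records(self, scenario_pop):
        pop, pheno = scenario_pop
        a = run_scenario1(pop, pheno, ["snp"], k=5, iters=1, seed=7)
        b = run_scenario1(pop, pheno, ["snp"], k=5, iters=1, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = run_scenario1(pop, pheno, ["snp"], k=5, iters=1, seed=8)
        assert not np.allclose(a["accuracy"], c["accuracy"])

    def test_methods_share_fold_assignments(self, scenario_pop):
        pop, pheno = scenario_pop
        rec = run_scenario1(pop, pheno, ["snp", "fixed:10"], k=5, iters=1, seed=3)
        # paired design: one record per method per fold
        counts = rec.groupby("replicate")["method"].nunique()
        assert (counts == 2).all()

    def test_too_many_folds_rejected(self, scenario_pop):
        pop, pheno = scenario_pop
        with pytest.raises(ValueError):
            run_scenario1(pop, pheno, ["snp"], k=pop.n_individuals + 1, iters=1, seed=1)


class TestScenarioAcross:
    def test_counts_determinism_and_disjoint_sampling(self, ke_pool, fv2):
        dh = hg.sim_dh_population(ke_pool, 60, seed=31)
        gc = hg.sim_gc_population(ke_pool, fv2.alleles, 60, seed=32)
        qtl = hg.additive_qtl_model(dh.n_snp, 40, seed=33)
        ph_dh = hg.sim_phenotypes(dh, qtl, 0.7, seed=34)
        ph_gc = hg.sim_phenotypes(gc, qtl, 0.7, seed=35)
        a = run_scenario_across(
            dh, ph_dh, gc, ph_gc, ["snp"], scenario=2, n_ts=40, n_ps=15, reps=4, seed=36
        )
        assert len(a) == 4
        b = run_scenario_across(
            dh, ph_dh, gc, ph_gc, ["snp"], scenario=2, n_ts=40, n_ps=15, reps=4, seed=36
        )
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            run_scenario_across(
                dh, ph_dh, gc, ph_gc, ["snp"], n_ts=61, n_ps=15, reps=1, seed=1
            )

    def test_haplib_with_fv2_in_gc_subgroup(self, ke_pool, fv2):
        dh = hg.sim_dh_population(ke_pool, 40, seed=41)
        gc = hg.sim_gc_population(ke_pool, fv2.alleles, 40, seed=42)
        qtl = hg.additive_qtl_model(dh.n_snp, 30, seed=43)
        ph_dh = hg.sim_phenotypes(dh, qtl, 0.7, seed=44)
        ph_gc = hg.sim_phenotypes(gc, qtl, 0.7, seed=45)
        rec = run_scenario_across(
            dh,
            ph_dh,
            gc,
            ph_gc,
            ["haplib:window=5,mcmb=50,min_subgroup=2"],
            scenario=2,
            n_ts=30,
            n_ps=10,
            reps=2,
            seed=46,
            fv2=fv2,
        )
        assert len(rec) == 2
        assert np.isfinite(rec["accuracy"]).all()


def tri(M):
    i, j = np.tril_indices(M.shape[0], k=-1)
    return M[i, j]


class TestMantel:
    def _random_sym(self, c, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(0, 1, (c, c))
        return A + A.T

    def test_identity_gives_r_one_minimal_p(self):
        A = self._random_sym(6, 0)
        r, p = mantel_test(A, A, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_negated_matrix_gives_minus_one(self):
        A = self._random_sym(6, 2)
        r, _ = mantel_test(A, -A, n_perm=9, seed=1)
        assert r == pytest.approx(-1.0)

    def test_r_matches_direct_lower_triangle_pearson(self):
        A, B = self._random_sym(8, 3), self._random_sym(8, 4)
        r, _ = mantel_test(A, B, n_perm=9, seed=1)
        want = np.corrcoef(tri(A), tri(B))[0, 1]
        assert r == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("c", [4, 5])
    def test_sampled_p_matches_exhaustive_enumeration(self, c):
        A, B = self._random_sym(c, 5), self._random_sym(c, 6)
        _, p_exact = mantel_test(A, B, exact=True)
        _, p_mc = mantel_test(A, B, n_perm=10_000, seed=7)
        assert abs(p_mc - p_exact) < 0.02

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            mantel_test(np.ones((5, 5)), np.eye(5))


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        a = np.arange(1.0, 7.0)
        w, p = signed_rank_test(a + 1.0, a)
        assert w == 21.0
        assert p == pytest.approx(2 / 64)

    def test_equal_samples_give_p_one(self):
        a = np.arange(8.0)
        assert wilcoxon_signed_rank(a, a) == 1.0

    def test_symmetric_differences_give_p_one(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert wilcoxon_signed_rank(a, np.zeros(6)) == 1.0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = rng.integers(5, 11)
            d = np.round(rng.normal(0, 2, n), 1)
            d = d[d != 0]
            if len(d) < 2:
                continue
            from scipy.stats import rankdata

            ranks = rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            # brute force over all 2^n sign assignments
            stats = [
                sum(r for r, s in zip(ranks, signs) if s)
                for signs in __import__("itertools").product([0, 1], repeat=len(d))
            ]
            stats = np.array(stats)
            cdf = (stats <= w_obs + 1e-9).mean()
            sf = (stats >= w_obs - 1e-9).mean()
            p_want = min(1.0, 2 * min(cdf, sf))
            w_got, p_got = signed_rank_test(d, np.zeros(len(d)))
            assert w_got == pytest.approx(w_obs)
            assert p_got == pytest.approx(p_want, abs=1e-9)

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(9)
        for _ in range(20):
            d = rng.normal(0, 1, 12)
            want = scipy_wilcoxon(d, alternative="two-sided", method="exact").pvalue
            assert wilcoxon_signed_rank(d, np.zeros(12)) == pytest.approx(want, abs=1e-10)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(10)
        d = rng.normal(0.3, 1, 60)
        from scipy.stats import wilcoxon as scipy_wilcoxon

        want = scipy_wilcoxon(
            d, alternative="two-sided", method="approx", correction=False
        ).pvalue
        assert wilcoxon_signed_rank(d, np.zeros(60)) == pytest.approx(want, rel=1e-6)


class TestBonferroni:
    def test_scaling_cap_and_identity(self):
        assert bonferroni([0.01], m=20)[0] == pytest.approx(0.2)
        assert bonferroni([0.2], m=20)[0] == 1.0
        assert bonferroni([0.3], m=1)[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bonferroni([0.01, 0.4]), [0.02, 0.8])
        with pytest.raises(ValueError):
            bonferroni([1.5])


def library_fixture():
    """Merged DH + GC + FV2 set with hand-placed whole-chromosome sequences.

    Sequence layout (one 10-SNP chromosome, window = chromosome):
      seq A: 10 DH gametes + 10 GC gametes (shared, common)
      seq B: 12 DH gametes + 6 GC gametes (shared, common)
      seq F: FV2's 2 gametes + 2 more GC gametes + 2 DH gametes
    Min-Subgroup <= 2 keeps seq F (2 DH carriers); any threshold above 2
    removes it, sending the FV2 composition to zero.
    """
    rng = np.random.default_rng(11)
    seq_a = rng.integers(0, 2, 10).astype(np.uint8)
    seq_b = 1 - seq_a
    seq_f = np.roll(seq_a, 3)
    if np.array_equal(seq_f, seq_a) or np.array_equal(seq_f, seq_b):
        raise AssertionError("fixture sequences must be distinct")
    rows, ind, pops = [], [], []

    def add(seq, n_ind, prefix, pop):
        for k in range(n_ind):
            rows.append(seq)
            rows.append(seq)
            ind.append(f"{prefix}{len(ind)}")
            pops.append(pop)

    add(seq_a, 5, "dh", "DH")   # 10 DH gametes
    add(seq_b, 6, "dh", "DH")   # 12 DH gametes
    add(seq_f, 1, "dh", "DH")   # 2 DH gametes carrying FV2's sequence
    add(seq_a, 5, "gc", "GC")   # 10 GC gametes
    add(seq_b, 3, "gc", "GC")   # 6 GC gametes
    add(seq_f, 1, "gc", "GC")   # 2 GC gametes carrying FV2's sequence
    rows.append(seq_f)
    rows.append(seq_f)
    ind.append("FV2")
    pops.append("GC")  # FV2 joins the GC subgroup during construction
    gmap = hg.uniform_map(10, n_chrom=1)
    gs = hg.GameteSet(np.array(rows), gmap, np.array(ind), np.array(pops))
    dh_ids = np.array([i for i, p in zip(ind, pops) if p == "DH"])
    return gs, dh_ids


class TestFV2Composition:
    def test_ratio_arithmetic_on_fixture(self):
        gs, dh_ids = library_fixture()
        lib = hg.build_library(gs, window=10, mcmb=1)
        # three alleles total; only seq F is carried by FV2 and present in DH
        assert lib.n_blocks == 3
        ratio = fv2_composition(lib, "FV2", dh_ids, gametes=gs)
        assert ratio == pytest.approx(1 / 3)

    def test_no_fv2_alleles_gives_zero(self, dh_pop):
        small = dh_pop.subset_snps(np.arange(20))
        lib = hg.build_library(small, window=10, mcmb=1)
        # pick a non-carrier id: FV2 absent means an error instead
        with pytest.raises(ValueError):
            fv2_composition(lib, "FV2", small.individuals, gametes=small)

    def test_single_universal_allele_gives_one(self):
        gmap = hg.uniform_map(4, n_chrom=1)
        seq = np.array([1, 0, 1, 0], dtype=np.uint8)
        alleles = np.tile(seq, (6, 1))
        gs = hg.GameteSet(
            alleles, gmap, np.array(["d1", "d2", "FV2"]), np.array(["DH", "DH", "GC"])
        )
        lib = hg.build_library(gs, window=4, mcmb=1)
        assert fv2_composition(lib, "FV2", np.array(["d1", "d2"]), gametes=gs) == 1.0

    def test_empty_library_rejected(self):
        gs, dh_ids = library_fixture()
        lib = hg.HaplotypeLibrary([], {})
        with pytest.raises(ValueError):
            fv2_composition(lib, "FV2", dh_ids, gametes=gs)


class TestTuneMinSubgroup:
    def test_recovers_planted_threshold(self):
        gs, dh_ids = library_fixture()
        labels = gs.gamete_populations()
        best, table = tune_min_subgroup(
            gs, labels, "FV2", dh_ids, candidates=(1, 2, 3, 5), mcmb=1, window=10
        )
        # composition is 1/3 at thresholds <= 2 and 0 above: smallest
        # minimizing candidate is 3
        assert best == 3
        comp = table.set_index("min_subgroup")["composition"]
        assert comp.loc[1] == pytest.approx(1 / 3)
        assert comp.loc[2] == pytest.approx(1 / 3)
        assert comp.loc[3] == 0.0

    def test_single_candidate_returned(self):
        gs, dh_ids = library_fixture()
        best, table = tune_min_subgroup(
            gs, gs.gamete_populations(), "FV2", dh_ids, candidates=(2,), mcmb=1, window=10
        )
        assert best == 2 and len(table) == 1

    def test_monotone_composition_returns_largest(self):
        gs, dh_ids = library_fixture()
        best, _ = tune_min_subgroup(
            gs, gs.gamete_populations(), "FV2", dh_ids, candidates=(1, 2), mcmb=1, window=10
        )
        # ties at 1/3 for both candidates: smallest wins
        assert best == 1

    def test_empty_candidates_rejected(self):
        gs, dh_ids = library_fixture()
        with pytest.raises(ValueError):
            tune_min_subgroup(gs, gs.gamete_populations(), "FV2", dh_ids, candidates=())


class TestHaplotypeAdvantage:
    def test_fixedhb_beats_snp_under_founder_haplotype_qtl(self):
        # local founder-haplotype effects are non-linear in single SNPs:
        # 20-SNP window alleles tag them, single markers cannot
        wins = 0
        n_rep = 8
        for rep in range(n_rep):
            gmap = dense_map(200)
            f = hg.sim_founders(10, 200, gmap=gmap, seed=1000 + rep)
            ke = f.subset(population="KE")
            dh = hg.sim_dh_population(ke, 100, seed=2000 + rep)
            qtl = hg.founder_qtl_model(ke, 20, region_size=20, seed=3000 + rep)
            ph = hg.sim_phenotypes(dh, qtl, 0.7, seed=4000 + rep)
            rec = run_scenario1(dh, ph, ["snp", "fixed:20"], k=5, iters=1, seed=5000 + rep)
            m = rec.groupby("method")["accuracy"].mean()
            wins += m["FixedHB(20)"] > m["SNP"]
        assert wins >= 0.6 * n_rep
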