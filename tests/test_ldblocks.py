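"""LD statistics and block-construction oracles.

D' is cross-checked against a brute-force oracle that scans the admissible
range of the joint haplotype frequency p11 (all four cell probabilities
non-negative) to find the extreme attainable D on the observed side — an
independent path to Dmax that never uses the closed form.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import haplogp as hg
from haplogp.ldblocks import (
    PairLD,
    dprime_ci,
    fixed_blocks,
    four_gamete_blocks,
    gabriel_blocks,
    pair_ld,
    spine_blocks,
)

from conftest import dense_map


def dprime_bruteforce(n11, n10, n01, n00, grid=200_001):
    """Oracle: D' by scanning admissible p11 values for the extreme D."""
    n = n11 + n10 + n01 + n00
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    d = n11 / n - pa * pb
    p11_grid = np.linspace(max(0.0, pa + pb - 1.0), min(pa, pb), grid)
    d_grid = p11_grid - pa * pb
    dmax = d_grid.max() if d >= 0 else -d_grid.min()
    return abs(d) / dmax


def random_tables(n_tables, seed, total=200):
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        t = rng.multinomial(total, rng.dirichlet(np.ones(4)))
        n11, n10, n01, n00 = t
        if 0 < n11 + n10 < total and 0 < n11 + n01 < total:  # both loci polymorphic
            tables.append(tuple(int(x) for x in t))
    return tables


class TestPairLD:
    def test_hand_computed_values(self):
        H = np.repeat(
            [[1, 1], [1, 0], [0, 1], [0, 0]], [40, 10, 10, 40], axis=0
        ).astype(np.uint8)
        p = pair_ld(H, 0, 1)
        assert p.d == pytest.approx(0.15)
        assert p.dprime == pytest.approx(0.6)

    def test_complete_ld_and_equilibrium(self):
        perfect = np.repeat([[1, 1], [0, 0]], [50, 50], axis=0).astype(np.uint8)
        assert pair_ld(perfect, 0, 1).dprime == pytest.approx(1.0)
        equi = np.repeat([[1, 1], [1, 0], [0, 1], [0, 0]], 25, axis=0).astype(np.uint8)
        p = pair_ld(equi, 0, 1)
        assert p.d == pytest.approx(0.0) and p.dprime == pytest.approx(0.0)

    def test_monomorphic_locus_rejected(self):
        H = np.array([[1, 1], [1, 0]], dtype=np.uint8)
        with pytest.raises(ValueError, match="monomorphic"):
            pair_ld(H, 0, 1)

    def test_matches_bruteforce_oracle(self):
        for n11, n10, n01, n00 in random_tables(300, seed=1):
            H = np.repeat(
                [[1, 1], [1, 0], [0, 1], [0, 0]], [n11, n10, n01, n00], axis=0
            ).astype(np.uint8)
            got = pair_ld(H, 0, 1).dprime
            want = dprime_bruteforce(n11, n10, n01, n00)
            assert got == pytest.approx(want, abs=1e-8)

    @given(st.integers(1, 60), st.integers(1, 60), st.integers(1, 60), st.integers(1, 60))
    @settings(max_examples=60, deadline=None)
    def test_duplication_leaves_dprime_unchanged(self, n11, n10, n01, n00):
        a = PairLD(n11, n10, n01, n00, 0, 0)
        H = np.repeat([[1, 1], [1, 0], [0, 1], [0, 0]], [n11, n10, n01, n00], axis=0).astype(
            np.uint8
        )
        H2 = np.vstack([H, H])
        assert pair_ld(H, 0, 1).dprime == pytest.approx(pair_ld(H2, 0, 1).dprime, abs=1e-12)


class TestDprimeCI:
    def test_overwhelming_evidence_tightens_lower_bound(self):
        lo, up = dprime_ci(PairLD(500, 0, 0, 500, 0, 0))
        assert lo >= 0.98 and up == pytest.approx(1.0)

    def test_tiny_sample_gives_wide_interval(self):
        lo, up = dprime_ci(PairLD(3, 3, 3, 3, 0, 0))
        assert lo < 0.7 and up - lo > 0.3

    def test_zero_mass_returns_mle_point(self):
        lo, up = dprime_ci(PairLD(40, 10, 10, 40, 0, 0), mass=0)
        assert lo == up == pytest.approx(0.6, abs=0.001)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            dprime_ci(PairLD(0, 0, 0, 0, 0, 0))


class TestFixedBlocks:
    def test_window_partition_exact(self):
        gmap = hg.uniform_map(100, n_chrom=1)
        part = fixed_blocks(gmap, 20)
        assert part.lengths().tolist() == [20] * 5

    def test_remainder_forms_short_tail(self):
        gmap = hg.uniform_map(11, n_chrom=1)
        assert fixed_blocks(gmap, 5).lengths().tolist() == [5, 5, 1]

    def test_window_one_is_per_snp(self, founders):
        part = fixed_blocks(founders.gmap, 1)
        assert part.n_blocks == founders.n_snp

    def test_blocks_never_span_chromosomes(self):
        gmap = hg.uniform_map(30, n_chrom=2)  # 15 + 15
        part = fixed_blocks(gmap, 10)
        assert part.lengths().tolist() == [10, 5, 10, 5]
        # coverage: every SNP assigned
        assert part.assigned_mask(30).all()


def planted_fixture(seed, n_clusters=3, cluster_size=5, n_hap=400):
    """Perfect-LD clusters separated by free recombination; truth known."""
    rng = np.random.default_rng(seed)
    m = n_clusters * cluster_size
    cols = []
    for _ in range(n_clusters):
        h0 = rng.integers(0, 2, cluster_size, dtype=np.uint8)
        hap = np.vstack([h0, 1 - h0])
        pick = rng.integers(0, 2, n_hap)
        cols.append(hap[pick])
    H = np.concatenate(cols, axis=1)
    gmap = hg.uniform_map(m, n_chrom=1)
    truth = [("chr1", i * cluster_size, (i + 1) * cluster_size) for i in range(n_clusters)]
    return H, gmap, truth


class TestLDBlockMethods:
    @pytest.mark.parametrize("seed", range(3))
    def test_all_methods_recover_planted_clusters(self, seed):
        H, gmap, truth = planted_fixture(seed)
        for fn in (gabriel_blocks, spine_blocks, four_gamete_blocks):
            part = fn(H, gmap)
            assert [(c, s, e) for c, s, e in part.blocks] == truth, fn.__name__

    def test_no_blocks_without_ld(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, (600, 8)).astype(np.uint8)
        gmap = hg.uniform_map(8, n_chrom=1)
        assert gabriel_blocks(H, gmap).n_blocks == 0
        assert spine_blocks(H, gmap).n_blocks == 0
        # equilibrium pair at frequency 0.25 each: boundary at every adjacency
        H4 = np.repeat([[1, 1], [1, 0], [0, 1], [0, 0]], 25, axis=0).astype(np.uint8)
        assert four_gamete_blocks(H4, hg.uniform_map(2, n_chrom=1)).n_blocks == 0

    def test_minimal_two_snp_block(self):
        H = np.repeat([[1, 1], [0, 0]], 250, axis=0).astype(np.uint8)
        part = gabriel_blocks(H, hg.uniform_map(2, n_chrom=1))
        assert part.blocks == [("chr1", 0, 2)]

    def test_four_gamete_zero_recombination_single_block(self):
        # two complementary founder haplotypes, no recombination: at most two
        # gamete classes per pair, so one block spans the chromosome
        rng = np.random.default_rng(5)
        h0 = rng.integers(0, 2, 12, dtype=np.uint8)
        H = np.vstack([np.tile(h0, (30, 1)), np.tile(1 - h0, (30, 1))])
        part = four_gamete_blocks(H, hg.uniform_map(12, n_chrom=1))
        assert part.blocks == [("chr1", 0, 12)]

    def test_four_gamete_cutoff_one_is_single_block(self, founders):
        small = founders.subset_snps(np.arange(30))
        part = four_gamete_blocks(small, small.gmap, cutoff=1.0)
        assert part.blocks == [("chr1", 0, 30)]

    def test_spine_stops_where_endpoint_ld_breaks(self):
        # SNPs 0..5 share perfect LD; SNP 6 recombines freely: the spine
        # extends to index 5 and no further
        rng = np.random.default_rng(6)
        h0 = rng.integers(0, 2, 6, dtype=np.uint8)
        hap = np.vstack([h0, 1 - h0])
        pick = rng.integers(0, 2, 500)
        left = hap[pick]
        right = rng.integers(0, 2, (500, 1)).astype(np.uint8)
        H = np.concatenate([left, right], axis=1)
        part = spine_blocks(H, hg.uniform_map(7, n_chrom=1))
        assert part.blocks[0] == ("chr1", 0, 6)

    def test_duplication_invariance(self):
        H, gmap, _ = planted_fixture(7)
        for fn in (gabriel_blocks, spine_blocks, four_gamete_blocks):
            a = fn(H, gmap).blocks
            b = fn(np.vstack([H, H]), gmap).blocks
            assert a == b, fn.__name__

    def test_dh_individuals_equal_duplicated_gametes(self, dh_pop):
        # on DH data every gamete appears twice; frequency-based quantities
        # (D', four-gamete boundaries) are identical whether each individual
        # contributes one or two copies.  CI-based methods sharpen with
        # sample size by construction, so only their saturated (well-powered)
        # behaviour is duplication-invariant (tested above on planted data).
        small = dh_pop.subset_snps(np.arange(40))
        once = small.alleles[0::2]
        assert (
            four_gamete_blocks(small, small.gmap).blocks
            == four_gamete_blocks(once, small.gmap).blocks
        )
        for j in range(10):
            a, b = 2 * j, 2 * j + 1
            try:
                d1 = pair_ld(small.alleles, a, b).dprime
                d2 = pair_ld(once, a, b).dprime
            except ValueError:
                continue
            assert d1 == pytest.approx(d2, abs=1e-12)
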