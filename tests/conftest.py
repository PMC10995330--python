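"""Shared fixtures: small simulated populations with realistic marker density.

Desk-scale maps shrink chromosome length together with SNP count so marker
density stays near the generator default (~6.7 SNP/cM); at much sparser
density, identity-by-descent sharing of whole SNP windows becomes rare and
the library methods degenerate for reasons unrelated to what the tests
check.
"""

import numpy as np
import pytest

import haplogp as hg


def dense_map(n_snp: int, n_chrom: int = 2) -> hg.GeneticMap:
    return hg.uniform_map(n_snp, n_chrom=n_chrom, cm_per_chrom=n_snp / n_chrom / 6.67)


@pytest.fixture(scope="session")
def founders():
    gmap = dense_map(300)
    return hg.sim_founders(n_founders_per_landrace=12, n_snp=300, gmap=gmap, seed=11)


@pytest.fixture(scope="session")
def ke_pool(founders):
    return founders.subset(population="KE")


@pytest.fixture(scope="session")
def dh_pop(ke_pool):
    return hg.sim_dh_population(ke_pool, 60, seed=12)


@pytest.fixture(scope="session")
def fv2(ke_pool):
    return hg.sim_capture_line(ke_pool.gmap, seed=13)


@pytest.fixture(scope="session")
def gc_pop(ke_pool, fv2):
    return hg.sim_gc_population(ke_pool, fv2.alleles, 60, seed=14)
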