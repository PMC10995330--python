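"""Pseudo-marker encoding of haplotype alleles and genomic relationship matrices.

Each haplotype allele (a distinct allele sequence over a block, or a library
block) becomes a pseudo-marker column coded 0/1/2 — the count of the
individual's gametes carrying it.  Relationship matrices follow VanRaden's
method 1, G = (X - 2P)(X - 2P)' / (2 * sum p_j (1 - p_j)), with observed
allele frequencies; a weighted variant scales each column by a per-haplotype
weight (genetic-map length, gene count or SNP count of the block).

With window-size-1 fixed blocks and no singleton filtering the haplotype GRM
reduces exactly to the SNP GRM: the two alleles of a SNP yield centered
columns z and -z, doubling numerator and denominator alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gametes import GameteSet
from .haplib import HaplotypeLibrary
from .ldblocks import BlockPartition

__all__ = [
    "PseudoMarkerMatrix",
    "GRM",
    "encode_alleles",
    "drop_singletons",
    "grm_vanraden",
    "grm_weighted",
    "haplotype_weights",
    "snp_grm",
]


@dataclass
class PseudoMarkerMatrix:
    """Individual x haplotype-allele dosage matrix with column metadata.

    ``meta`` columns: locus, allele, chrom, start, end, n_snps, cm_span and
    (when a gene track is supplied) n_genes.  For partition-based loci the
    per-locus row sums are 2 for every individual.
    """

    M: np.ndarray
    meta: pd.DataFrame
    individuals: np.ndarray

    def __post_init__(self):
        if self.M.shape != (len(self.individuals), len(self.meta)):
            raise ValueError("matrix shape inconsistent with metadata/ids")

    @property
    def n_individuals(self) -> int:
        return self.M.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.M.shape[1]

    def subset_individuals(self, ids) -> "PseudoMarkerMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        idx = np.array([pos[i] for i in ids])
        return PseudoMarkerMatrix(self.M[idx], self.meta, np.asarray(ids))


@dataclass
class GRM:
    """Symmetric realized relationship matrix with individual ids."""

    values: np.ndarray
    ids: np.ndarray
    kind: str = "SNP"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("GRM must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def is_psd(self, rel_tol: float = 1e-8) -> bool:
        return self.min_eigenvalue() >= -rel_tol * np.trace(self.values) / self.n

    def submatrix(self, ids) -> "GRM":
        pos = {ind: i for i, ind in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return GRM(self.values[np.ix_(idx, idx)], np.asarray(ids), self.kind)

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str, kind: str = "GRM") -> "GRM":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), df.index.to_numpy(), kind)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _gene_counts(meta: pd.DataFrame, gmap, gene_track: pd.DataFrame) -> np.ndarray:
    """Gene intervals (BED half-open) overlapping each block's bp span."""
    counts = np.zeros(len(meta), dtype=int)
    for c, grp in gene_track.groupby("chrom"):
        sel = meta["chrom"] == c
        if not sel.any():
            continue
        s_bp = gmap.bp[meta.loc[sel, "start"].to_numpy()] - 1  # 0-based
        e_bp = gmap.bp[meta.loc[sel, "end"].to_numpy() - 1]  # exclusive
        gs = grp["start"].to_numpy()
        ge = grp["end"].to_numpy()
        counts[np.flatnonzero(sel.to_numpy())] = (
            (gs[None, :] < e_bp[:, None]) & (ge[None, :] > s_bp[:, None])
        ).sum(axis=1)
    return counts


def encode_alleles(
    blocks, gametes: GameteSet, gene_track: pd.DataFrame | None = None
) -> PseudoMarkerMatrix:
    """Haplotype alleles as 0/1/2 pseudo-marker dosages.

    Partition mode (BlockPartition): one column per distinct observed allele
    sequence per block; every individual's two gametes each carry exactly one
    allele per block, so per-locus row sums are 2.  Library mode
    (HaplotypeLibrary): one column per block, the count of the individual's
    gametes in the block's carrier set (blocks may overlap, so no row-sum
    constraint holds).
    """
    if gametes.has_missing:
        raise ValueError("encoding requires complete genotypes")
    H = gametes.alleles
    n_ind = gametes.n_individuals
    cols, meta_rows = [], []
    if isinstance(blocks, BlockPartition):
        for locus, (c, s, e) in enumerate(blocks.blocks):
            sub = H[:, s:e]
            uniq, inv = np.unique(sub, axis=0, return_inverse=True)
            inv2 = inv.reshape(n_ind, 2)
            for a in range(len(uniq)):
                cols.append((inv2 == a).sum(axis=1))
                meta_rows.append((locus, a, c, s, e))
    elif isinstance(blocks, HaplotypeLibrary):
        for locus, b in enumerate(blocks.blocks):
            dose = np.bincount(b.carriers // 2, minlength=n_ind)
            cols.append(dose)
            meta_rows.append((locus, 0, b.chrom, b.start, b.end))
    else:
        raise TypeError("blocks must be a BlockPartition or HaplotypeLibrary")
    if not cols:
        raise ValueError("no haplotype alleles to encode")
    M = np.column_stack(cols).astype(np.int16)
    meta = pd.DataFrame(meta_rows, columns=["locus", "allele", "chrom", "start", "end"])
    gmap = gametes.gmap
    meta["n_snps"] = meta["end"] - meta["start"]
    meta["cm_span"] = gmap.cm[meta["end"].to_numpy() - 1] - gmap.cm[meta["start"].to_numpy()]
    if gene_track is not None:
        meta["n_genes"] = _gene_counts(meta, gmap, gene_track)
    return PseudoMarkerMatrix(M, meta, gametes.individuals.copy())


def drop_singletons(pmm: PseudoMarkerMatrix, population_ids=None) -> PseudoMarkerMatrix:
    """Drop alleles carried by exactly one individual of the analysis population.

    ``population_ids`` restricts the carrier count to a subset of individuals
    (default: all); columns whose number of carrier individuals *within that
    population* equals 1 are removed.
    """
    if population_ids is None:
        rows = np.arange(pmm.n_individuals)
    else:
        pos = {ind: i for i, ind in enumerate(pmm.individuals)}
        rows = np.array([pos[i] for i in population_ids])
    carriers = (pmm.M[rows] > 0).sum(axis=0)
    keep = carriers != 1
    return PseudoMarkerMatrix(
        pmm.M[:, keep], pmm.meta.loc[keep].reset_index(drop=True), pmm.individuals
    )


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def _dosage_and_ids(X, ids):
    if isinstance(X, PseudoMarkerMatrix):
        return X.M.astype(np.float64), X.individuals
    X = np.asarray(X, dtype=np.float64)
    if ids is None:
        ids = np.arange(X.shape[0])
    return X, np.asarray(ids)


def grm_vanraden(X, ids=None, freqs=None, kind: str = "haplotype") -> GRM:
    """VanRaden method-1 relationship matrix from a 0/1/2 dosage matrix.

    G = (X - 2P)(X - 2P)' / (2 * sum_j p_j (1 - p_j)) with p_j the observed
    column frequency (column mean / 2) unless ``freqs`` is given.
    Monomorphic columns center to zero and are excluded from the denominator;
    if every column is monomorphic the matrix is undefined.
    """
    X, ids = _dosage_and_ids(X, ids)
    if X.shape[0] < 2:
        raise ValueError("need at least two individuals")
    p = X.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=np.float64)
    poly = (p > 0) & (p < 1)
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    if denom == 0:
        raise ValueError("all columns monomorphic: GRM undefined")
    Z = X - 2.0 * p
    return GRM(Z @ Z.T / denom, ids, kind)


def grm_weighted(X, weights, ids=None, kind: str = "weighted") -> GRM:
    """Weighted VanRaden GRM: G = Z W Z' / (2 * sum_j w_j p_j (1 - p_j)).

    ``weights`` (>= 0, one per column, not all zero) are normalized to mean 1
    so the all-equal case reduces exactly to the unweighted GRM.
    """
    X, ids = _dosage_and_ids(X, ids)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (X.shape[1],):
        raise ValueError("one weight per column required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    w = w / w.mean()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    denom = 2.0 * np.sum(w[poly] * p[poly] * (1 - p[poly]))
    if denom == 0:
        raise ValueError("all columns monomorphic: GRM undefined")
    Z = X - 2.0 * p
    return GRM((Z * w) @ Z.T / denom, ids, kind)


def haplotype_weights(meta: pd.DataFrame, mode: str) -> np.ndarray:
    """Per-haplotype weights from block metadata.

    Modes: ``cM_length`` (genetic-map span; zero-length spans are floored at
    the minimum positive observed span), ``n_genes`` (gene intervals
    overlapped), ``n_snps`` (SNPs in the block).
    """
    if mode == "cM_length":
        w = meta["cm_span"].to_numpy(dtype=float).copy()
        pos = w[w > 0]
        if len(pos) == 0:
            raise ValueError("all cM spans are zero")
        w[w == 0] = pos.min()
        return w
    if mode == "n_genes":
        if "n_genes" not in meta:
            raise ValueError("metadata has no gene counts (encode with a gene track)")
        w = meta["n_genes"].to_numpy(dtype=float)
        if w.sum() == 0:
            raise ValueError("gene track overlaps no block: all-zero weights")
        return w
    if mode == "n_snps":
        return meta["n_snps"].to_numpy(dtype=float)
    raise ValueError(f"unknown weight mode {mode!r}")


def snp_grm(gametes: GameteSet) -> GRM:
    """VanRaden method-1 GRM straight from the SNP dosage matrix."""
    return grm_vanraden(gametes.dosage(), ids=gametes.individuals, kind="SNP")
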