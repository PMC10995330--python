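"""Haplotype-block construction from fixed windows or pairwise LD.

Implements four ways of grouping SNPs into non-overlapping haplotype loci:

* fixed windows of adjacent SNPs (FixedHB);
* confidence-interval blocks (GAB): SNP pairs are in "strong LD" when the
  likelihood-based confidence interval of D' has an upper bound >= 0.98 and
  a lower bound >= 0.70, and an interval qualifies as a block when >= 95% of
  its within-interval pairs are strong;
* the four-gamete rule (4GAM): an adjacent pair is in LD when one of its
  four two-marker gamete classes has frequency below 0.01, and blocks are
  maximal runs of in-LD adjacencies;
* solid spine of LD (SPINE): a block grows to the right while its first and
  last SNP remain in strong LD.

All LD is computed from direct phased-gamete counts — no EM is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy
from sklearn.base import BaseEstimator

from .gametes import GameteSet, GeneticMap

__all__ = [
    "BlockPartition",
    "PairLD",
    "pair_ld",
    "dprime_ci",
    "fixed_blocks",
    "gabriel_blocks",
    "four_gamete_blocks",
    "spine_blocks",
    "FixedBlocker",
    "GabrielBlocker",
    "FourGameteBlocker",
    "SpineBlocker",
]


@dataclass
class BlockPartition:
    """Ordered, non-overlapping [start, end) SNP-index intervals per chromosome.

    ``blocks`` hold global SNP indices; fixed-window partitions cover every
    SNP, LD-based methods may leave SNPs unassigned.
    """

    blocks: list  # [(chrom, start, end), ...]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        last_end = {}
        for c, s, e in self.blocks:
            if e <= s:
                raise ValueError("empty block interval")
            if s < last_end.get(c, -1):
                raise ValueError("blocks overlap or are unsorted")
            last_end[c] = e

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def lengths(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.blocks], dtype=int)

    def assigned_mask(self, n_snp: int) -> np.ndarray:
        mask = np.zeros(n_snp, dtype=bool)
        for _, s, e in self.blocks:
            mask[s:e] = True
        return mask

    def to_frame(self, gmap: GeneticMap):
        import pandas as pd

        rows = [
            (c, int(gmap.bp[s]) - 1, int(gmap.bp[e - 1]), s, e, self.method)
            for c, s, e in self.blocks
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start_bp", "end_bp", "start_idx", "end_idx", "method"]
        )


@dataclass
class PairLD:
    """Two-locus gamete counts with D and D' for one SNP pair."""

    n11: int
    n10: int
    n01: int
    n00: int
    d: float
    dprime: float
    ci_lower: float | None = None
    ci_upper: float | None = None


def _gamete_matrix(gametes) -> np.ndarray:
    if isinstance(gametes, GameteSet):
        if gametes.has_missing:
            raise ValueError("LD requires complete genotypes")
        return gametes.alleles
    return np.asarray(gametes, dtype=np.uint8)


def pair_ld(gametes, i: int, j: int) -> PairLD:
    """D and D' for one SNP pair from direct phased-gamete counts.

    D = p11 - pA*pB; D' = |D| / Dmax where Dmax is the largest |D| the
    observed allele frequencies admit on the side of the observed sign.
    """
    H = _gamete_matrix(gametes)
    a, b = H[:, i].astype(np.int64), H[:, j].astype(np.int64)
    n11 = int((a & b).sum())
    n10 = int((a & (1 - b)).sum())
    n01 = int(((1 - a) & b).sum())
    n00 = len(a) - n11 - n10 - n01
    d, dp = _d_dprime(n11, n10, n01, n00)
    return PairLD(n11, n10, n01, n00, d, dp)


def _d_dprime(n11, n10, n01, n00):
    n = n11 + n10 + n01 + n00
    if n == 0:
        raise ValueError("zero total gamete count")
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("D' undefined: monomorphic locus")
    d = n11 / n - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    return d, abs(d) / dmax


def dprime_ci(pairld: PairLD, grid_step: float = 0.001, mass: float = 0.90) -> tuple[float, float]:
    """Likelihood-based confidence bounds for D' on a [0, 1] grid.

    Allele frequencies are held at their observed values; every grid value of
    D' maps to a two-locus haplotype-probability table whose multinomial
    likelihood of the observed counts is evaluated.  The normalized
    likelihood mass is treated as a distribution over the grid and the
    central ``mass`` interval is returned ((1-mass)/2 in each tail);
    ``mass=0`` collapses to the maximum-likelihood grid point.
    """
    counts = np.array([[pairld.n11, pairld.n10, pairld.n01, pairld.n00]], dtype=np.float64)
    lo, up = _ci_bounds(counts, grid_step, mass)
    return float(lo[0]), float(up[0])


def _ci_bounds(counts: np.ndarray, grid_step: float, mass: float):
    """Vectorized D' confidence bounds; ``counts`` is (k, 4) of n11,n10,n01,n00."""
    n = counts.sum(axis=1)
    if np.any(n == 0):
        raise ValueError("zero total gamete count")
    pa = (counts[:, 0] + counts[:, 1]) / n
    pb = (counts[:, 0] + counts[:, 2]) / n
    if np.any((pa == 0) | (pa == 1) | (pb == 0) | (pb == 1)):
        raise ValueError("D' undefined: monomorphic locus")
    d = counts[:, 0] / n - pa * pb
    dmax = np.where(
        d >= 0,
        np.minimum(pa * (1 - pb), (1 - pa) * pb),
        np.minimum(pa * pb, (1 - pa) * (1 - pb)),
    )
    sign = np.where(d >= 0, 1.0, -1.0)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    # (k, G) haplotype probabilities at each grid D'
    p11 = pa[:, None] * pb[:, None] + (sign * dmax)[:, None] * grid[None, :]
    p10 = pa[:, None] - p11
    p01 = pb[:, None] - p11
    p00 = 1.0 - pa[:, None] - pb[:, None] + p11
    ll = (
        xlogy(counts[:, 0, None], np.clip(p11, 0.0, None))
        + xlogy(counts[:, 1, None], np.clip(p10, 0.0, None))
        + xlogy(counts[:, 2, None], np.clip(p01, 0.0, None))
        + xlogy(counts[:, 3, None], np.clip(p00, 0.0, None))
    )
    w = np.exp(ll - ll.max(axis=1, keepdims=True))
    if mass == 0:
        mle = grid[np.argmax(w, axis=1)]
        return mle, mle
    cum = np.cumsum(w, axis=1)
    tot = cum[:, -1]
    alpha = (1.0 - mass) / 2.0
    lo_idx = np.array(
        [np.searchsorted(cum[k], alpha * tot[k], side="right") for k in range(len(tot))]
    )
    up_idx = np.array(
        [np.searchsorted(cum[k], (1 - alpha) * tot[k], side="left") for k in range(len(tot))]
    )
    up_idx = np.minimum(up_idx, len(grid) - 1)
    return grid[lo_idx], grid[up_idx]


# ---------------------------------------------------------------------------
# fixed windows
# ---------------------------------------------------------------------------

def fixed_blocks(gmap: GeneticMap, window_size: int) -> BlockPartition:
    """Non-overlapping windows of ``window_size`` adjacent SNPs per chromosome.

    The final window of a chromosome may be shorter; blocks never span
    chromosome boundaries and every SNP is assigned.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if gmap.n_snp == 0:
        raise ValueError("empty map")
    blocks = []
    for c, sl in gmap.chrom_slices().items():
        for s in range(sl.start, sl.stop, window_size):
            blocks.append((c, s, min(s + window_size, sl.stop)))
    return BlockPartition(blocks, "FixedHB", {"window_size": window_size})


# ---------------------------------------------------------------------------
# strong-LD machinery shared by GAB and SPINE
# ---------------------------------------------------------------------------

def _strong_ld_matrix(
    H: np.ndarray,
    ci_lower: float,
    ci_upper: float,
    grid_step: float = 0.001,
    mass: float = 0.90,
    max_span: int | None = None,
    chunk: int = 4096,
) -> np.ndarray:
    """Symmetric boolean matrix: pair (i, j) in strong LD by the CI rule.

    Pairs involving a monomorphic SNP are never strong.  ``max_span``
    optionally caps the index distance of evaluated pairs (the HaploView-style
    physical-distance cap, off by default).
    """
    Hi = H.astype(np.int64)
    m = H.shape[1]
    n = H.shape[0]
    s = Hi.sum(axis=0)
    poly = (s > 0) & (s < n)
    c11 = Hi.T @ Hi
    ii, jj = np.triu_indices(m, k=1)
    keep = poly[ii] & poly[jj]
    if max_span is not None:
        keep &= (jj - ii) <= max_span
    ii, jj = ii[keep], jj[keep]
    strong = np.zeros((m, m), dtype=bool)
    for k0 in range(0, len(ii), chunk):
        i = ii[k0 : k0 + chunk]
        j = jj[k0 : k0 + chunk]
        n11 = c11[i, j]
        counts = np.column_stack([n11, s[i] - n11, s[j] - n11, n - s[i] - s[j] + n11]).astype(
            np.float64
        )
        lo, up = _ci_bounds(counts, grid_step, mass)
        ok = (up >= ci_upper) & (lo >= ci_lower)
        strong[i[ok], j[ok]] = True
        strong[j[ok], i[ok]] = True
    return strong


def gabriel_blocks(
    gametes,
    gmap: GeneticMap,
    ci_lower: float = 0.70,
    ci_upper: float = 0.98,
    frac: float = 0.95,
    min_block: int = 2,
    mass: float = 0.90,
    grid_step: float = 0.001,
    max_span: int | None = None,
) -> BlockPartition:
    """Confidence-interval LD blocks.

    An interval qualifies when at least ``frac`` of all its within-interval
    pairs are strong-LD; maximal qualifying intervals are accepted greedily
    from longest to shortest (ties to the leftmost start), skipping overlap
    with already-accepted blocks.
    """
    H = _gamete_matrix(gametes)
    blocks = []
    for c, sl in gmap.chrom_slices().items():
        Hc = H[:, sl]
        m = Hc.shape[1]
        if m < min_block:
            continue
        S = _strong_ld_matrix(Hc, ci_lower, ci_upper, grid_step, mass, max_span)
        # strong_cnt[a, b] = number of strong pairs within [a, b]
        col_cum = np.cumsum(S, axis=0)  # col_cum[i, b] = sum of S[:i+1, b]
        cands = []
        cnt = np.zeros(m)  # cnt[a] = strong pairs in [a, b] for current b
        for b in range(1, m):
            # extend every interval's right edge to b
            add = col_cum[b - 1, b] - np.concatenate(([0.0], col_cum[: b - 1 + 1, b][:-1]))
            # add[a] = sum S[a..b-1, b]
            cnt[:b] += add[:b]
            lens = b - np.arange(b) + 1
            sel = np.flatnonzero(lens >= min_block)
            tot = lens[sel] * (lens[sel] - 1) / 2
            ok = sel[cnt[sel] >= frac * tot]
            for a in ok:
                cands.append((int(b - a + 1), int(a), int(b)))
        cands.sort(key=lambda t: (-t[0], t[1]))
        occupied = np.zeros(m, dtype=bool)
        accepted = []
        for L, a, b in cands:
            if not occupied[a : b + 1].any():
                occupied[a : b + 1] = True
                accepted.append((a, b))
        for a, b in sorted(accepted):
            blocks.append((c, sl.start + a, sl.start + b + 1))
    params = {"ci_lower": ci_lower, "ci_upper": ci_upper, "frac": frac, "min_block": min_block}
    return BlockPartition(blocks, "GAB", params)


def four_gamete_blocks(gametes, gmap: GeneticMap, cutoff: float = 0.01) -> BlockPartition:
    """Four-gamete-rule blocks over consecutive markers.

    An adjacent pair is "in LD" when its rarest two-marker gamete class has
    frequency below ``cutoff`` (i.e. fewer than four gamete classes are
    credibly present, so no recombination between the pair is evident).
    Blocks are maximal runs of in-LD adjacencies; isolated SNPs stay
    unassigned.
    """
    H = _gamete_matrix(gametes).astype(np.int64)
    n = H.shape[0]
    blocks = []
    for c, sl in gmap.chrom_slices().items():
        Hc = H[:, sl]
        m = Hc.shape[1]
        if m < 2:
            continue
        x, y = Hc[:, :-1], Hc[:, 1:]
        n11 = (x & y).sum(axis=0)
        n10 = (x & (1 - y)).sum(axis=0)
        n01 = ((1 - x) & y).sum(axis=0)
        n00 = n - n11 - n10 - n01
        fmin = np.minimum.reduce([n11, n10, n01, n00]) / n
        in_ld = fmin < cutoff
        j = 0
        while j < m - 1:
            if in_ld[j]:
                k = j
                while k < m - 1 and in_ld[k]:
                    k += 1
                blocks.append((c, sl.start + j, sl.start + k + 1))
                j = k + 1
            else:
                j += 1
    return BlockPartition(blocks, "4GAM", {"cutoff": cutoff})


def spine_blocks(
    gametes,
    gmap: GeneticMap,
    ci_lower: float = 0.70,
    ci_upper: float = 0.98,
    mass: float = 0.90,
    grid_step: float = 0.001,
    max_span: int | None = None,
) -> BlockPartition:
    """Solid-spine-of-LD blocks.

    Scanning left to right, a block's right edge is extended while the pair
    (first SNP, candidate last SNP) is strong LD by the same CI criterion as
    the GAB method; intermediate pairs are not required to be in LD.
    """
    H = _gamete_matrix(gametes)
    blocks = []
    for c, sl in gmap.chrom_slices().items():
        Hc = H[:, sl]
        m = Hc.shape[1]
        if m < 2:
            continue
        S = _strong_ld_matrix(Hc, ci_lower, ci_upper, grid_step, mass, max_span)
        i = 0
        while i < m - 1:
            j = i
            while j + 1 < m and S[i, j + 1]:
                j += 1
            if j > i:
                blocks.append((c, sl.start + i, sl.start + j + 1))
                i = j + 1
            else:
                i += 1
    return BlockPartition(blocks, "SPINE", {"ci_lower": ci_lower, "ci_upper": ci_upper})


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class _BlockerBase(BaseEstimator):
    """Fit on a GameteSet; the resulting partition lands in ``partition_``."""

    def fit(self, gametes: GameteSet, y=None):
        self.partition_ = self._build(gametes)
        self.n_blocks_ = self.partition_.n_blocks
        return self

    def fit_transform(self, gametes: GameteSet, y=None):
        return self.fit(gametes).partition_


class FixedBlocker(_BlockerBase):
    def __init__(self, window_size: int = 20):
        self.window_size = window_size

    def _build(self, gametes):
        return fixed_blocks(gametes.gmap, self.window_size)


class GabrielBlocker(_BlockerBase):
    def __init__(self, ci_lower=0.70, ci_upper=0.98, frac=0.95, min_block=2, max_span=None):
        self.ci_lower = ci_lower
        self.ci_upper = ci_upper
        self.frac = frac
        self.min_block = min_block
        self.max_span = max_span

    def _build(self, gametes):
        return gabriel_blocks(
            gametes,
            gametes.gmap,
            ci_lower=self.ci_lower,
            ci_upper=self.ci_upper,
            frac=self.frac,
            min_block=self.min_block,
            max_span=self.max_span,
        )


class FourGameteBlocker(_BlockerBase):
    def __init__(self, cutoff: float = 0.01):
        self.cutoff = cutoff

    def _build(self, gametes):
        return four_gamete_blocks(gametes, gametes.gmap, cutoff=self.cutoff)


class SpineBlocker(_BlockerBase):
    def __init__(self, ci_lower=0.70, ci_upper=0.98, max_span=None):
        self.ci_lower = ci_lower
        self.ci_upper = ci_upper
        self.max_span = max_span

    def _build(self, gametes):
        return spine_blocks(
            gametes,
            gametes.gmap,
            ci_lower=self.ci_lower,
            ci_upper=self.ci_upper,
            max_span=self.max_span,
        )
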