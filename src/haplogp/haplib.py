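"""Identity-by-descent haplotype library construction.

Builds a library of variable-length haplotype blocks by seeding clusters of
gametes with identical allele sequences in fixed SNP windows, extending each
cluster left and right while all carriers keep agreeing (exact matching;
no merging error, matching array-quality data), and filtering the candidate
blocks by (i) a minimum number of cells — block SNP length times carrier
count (MCMB), (ii) a minimum carrier count in every predefined subgroup
(Min Subgroup), or (iii) a genome-coverage target that selects the MCMB
value automatically.  Coverage is the fraction of gamete x SNP cells covered
by at least one retained block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .gametes import GameteSet

__all__ = [
    "HaplotypeBlock",
    "HaplotypeLibrary",
    "window_clusters",
    "extend_blocks",
    "filter_mcmb",
    "filter_min_subgroup",
    "build_library",
    "HaplotypeLibraryBuilder",
]


@dataclass
class HaplotypeBlock:
    """One haplotype allele: an allele sequence over [start, end) with its carriers."""

    chrom: object
    start: int
    end: int
    alleles: np.ndarray  # uint8, length end - start
    carriers: np.ndarray  # sorted gamete row indices

    @property
    def n_snp(self) -> int:
        return self.end - self.start

    @property
    def cells(self) -> int:
        return self.n_snp * len(self.carriers)

    def matches(self, H: np.ndarray) -> bool:
        """Audit: every carrier matches the allele sequence exactly."""
        return bool((H[self.carriers, self.start : self.end] == self.alleles).all())


@dataclass
class HaplotypeLibrary:
    blocks: list
    params: dict = field(default_factory=dict)
    coverage: float = 0.0

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def compute_coverage(self, n_gametes: int, n_snp: int) -> float:
        covered = np.zeros((n_gametes, n_snp), dtype=bool)
        for b in self.blocks:
            covered[b.carriers, b.start : b.end] = True
        return float(covered.sum()) / (n_gametes * n_snp)

    def to_frame(self, subgroup_labels=None):
        import pandas as pd

        rows = []
        for b in self.blocks:
            row = {
                "chrom": b.chrom,
                "start_idx": b.start,
                "end_idx": b.end,
                "alleles": "".join(map(str, b.alleles)),
                "n_carriers": len(b.carriers),
                "cells": b.cells,
            }
            if subgroup_labels is not None:
                labels = np.asarray(subgroup_labels)
                for g in np.unique(labels):
                    row[f"carriers_{g}"] = int((labels[b.carriers] == g).sum())
            rows.append(row)
        return pd.DataFrame(rows)


def _matrix_and_slices(gametes: GameteSet):
    if gametes.has_missing:
        raise ValueError("library construction requires complete genotypes")
    return gametes.alleles, gametes.gmap.chrom_slices()


def window_clusters(gametes: GameteSet, w: int) -> list[HaplotypeBlock]:
    """Seed blocks: gametes grouped by identical sequence in w-SNP windows.

    Windows tile each chromosome; a short tail window is kept.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    H, slices = _matrix_and_slices(gametes)
    seeds = []
    for c, sl in slices.items():
        for s in range(sl.start, sl.stop, w):
            e = min(s + w, sl.stop)
            sub = H[:, s:e]
            uniq, inv = np.unique(sub, axis=0, return_inverse=True)
            for a in range(len(uniq)):
                carriers = np.flatnonzero(inv == a)
                seeds.append(HaplotypeBlock(c, s, e, uniq[a].copy(), carriers))
    return seeds


def extend_blocks(
    seeds: list[HaplotypeBlock], gametes: GameteSet, merging_error: int = 0
) -> list[HaplotypeBlock]:
    """Extend seed blocks while all carriers agree on the next SNP.

    Only exact matching (``merging_error = 0``) is supported.  After
    extension, carriers are recomputed as *all* gametes matching the extended
    sequence, duplicates (same interval and sequence) are collapsed, and
    blocks nested inside a strictly longer block with the same carrier set
    are removed.
    """
    if merging_error != 0:
        raise ValueError("only merging_error=0 (exact matching) is supported")
    H, slices = _matrix_and_slices(gametes)
    bounds = {c: (sl.start, sl.stop) for c, sl in slices.items()}
    out = {}
    for seed in seeds:
        lo, hi = bounds[seed.chrom]
        s, e = seed.start, seed.end
        carriers = seed.carriers
        while s > lo:
            col = H[carriers, s - 1]
            if (col == col[0]).all():
                s -= 1
            else:
                break
        while e < hi:
            col = H[carriers, e]
            if (col == col[0]).all():
                e += 1
            else:
                break
        alleles = H[carriers[0], s:e].copy()
        key = (seed.chrom, s, e, alleles.tobytes())
        if key not in out:
            full = np.flatnonzero((H[:, s:e] == alleles).all(axis=1))
            out[key] = HaplotypeBlock(seed.chrom, s, e, alleles, full)
    # nested removal: same carriers, strictly contained interval
    by_carriers = {}
    for b in out.values():
        by_carriers.setdefault((b.chrom, b.carriers.tobytes()), []).append(b)
    kept = []
    for group in by_carriers.values():
        for b in group:
            nested = any(
                (o.start <= b.start and b.end <= o.end and o.n_snp > b.n_snp) for o in group
            )
            if not nested:
                kept.append(b)
    kept.sort(key=lambda b: (str(b.chrom), b.start, b.end, b.alleles.tobytes()))
    return kept


def filter_mcmb(blocks, mcmb: int, gametes: GameteSet, params: dict | None = None) -> HaplotypeLibrary:
    """Keep blocks with at least ``mcmb`` cells (SNP length x carrier count)."""
    if mcmb < 1:
        raise ValueError("mcmb must be >= 1")
    if isinstance(blocks, HaplotypeLibrary):
        blocks = blocks.blocks
    kept = [b for b in blocks if b.cells >= mcmb]
    lib = HaplotypeLibrary(kept, dict(params or {}, mcmb=mcmb))
    lib.coverage = lib.compute_coverage(gametes.n_gametes, gametes.n_snp)
    return lib


def filter_min_subgroup(
    library: HaplotypeLibrary, subgroup_labels, threshold: int, gametes: GameteSet
) -> HaplotypeLibrary:
    """Keep blocks whose carrier count within every subgroup is >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    labels = np.asarray(subgroup_labels)
    if len(labels) != gametes.n_gametes:
        raise ValueError("one subgroup label per gamete required")
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels.tolist()):
        raise ValueError("every gamete must carry a subgroup label")
    if threshold == 0:
        return library
    groups = np.unique(labels)
    kept = []
    for b in library.blocks:
        carr = labels[b.carriers]
        if all((carr == g).sum() >= threshold for g in groups):
            kept.append(b)
    lib = HaplotypeLibrary(kept, dict(library.params, min_subgroup=threshold))
    lib.coverage = lib.compute_coverage(gametes.n_gametes, gametes.n_snp)
    return lib


def build_library(
    gametes: GameteSet,
    window: int | list = 20,
    mcmb: int = 5000,
    target_coverage: float | None = None,
    subgroup_labels=None,
    min_subgroup: int = 0,
) -> HaplotypeLibrary:
    """Full pipeline: seed, extend, Min-Subgroup filter, then MCMB filter.

    ``window`` may be a list of window sizes (multi-window mode: candidate
    blocks are pooled over all sizes and deduplicated).  If
    ``target_coverage`` is given it drives the filtering instead of
    ``mcmb``: the retained-cells threshold is found by bisection over the
    distinct block cell counts so that achieved coverage is the smallest
    coverage >= target.  If even a threshold of 1 cannot reach the target,
    the threshold-1 library is returned flagged ``target_unreachable``.
    """
    windows = list(window) if isinstance(window, (list, tuple)) else [window]
    if target_coverage is not None and not 0 < target_coverage < 1:
        raise ValueError("target_coverage must lie in (0, 1)")
    seeds = []
    for w in windows:
        seeds.extend(window_clusters(gametes, w))
    candidates = extend_blocks(seeds, gametes)
    params = {"window": windows if len(windows) > 1 else windows[0], "min_subgroup": min_subgroup}
    base = HaplotypeLibrary(candidates, params)
    if min_subgroup > 0:
        if subgroup_labels is None:
            raise ValueError("min_subgroup > 0 requires subgroup labels")
        base = filter_min_subgroup(base, subgroup_labels, min_subgroup, gametes)

    if target_coverage is None:
        return filter_mcmb(base.blocks, mcmb, gametes, base.params)

    cells = sorted({b.cells for b in base.blocks})
    if not cells:
        lib = filter_mcmb(base.blocks, 1, gametes, base.params)
        lib.params["target_unreachable"] = True
        warnings.warn("empty candidate set: target coverage unreachable")
        return lib
    # largest cell threshold whose coverage still meets the target
    lo_lib = filter_mcmb(base.blocks, 1, gametes, base.params)
    if lo_lib.coverage < target_coverage:
        lo_lib.params["target_unreachable"] = True
        lo_lib.params["target_coverage"] = target_coverage
        warnings.warn("target coverage unreachable even at mcmb=1")
        return lo_lib
    lo, hi = 0, len(cells) - 1  # indices into sorted distinct cell counts
    best = lo_lib
    while lo <= hi:
        mid = (lo + hi) // 2
        lib = filter_mcmb(base.blocks, cells[mid], gametes, base.params)
        if lib.coverage >= target_coverage:
            best = lib
            lo = mid + 1
        else:
            hi = mid - 1
    best.params["target_coverage"] = target_coverage
    return best


class HaplotypeLibraryBuilder(BaseEstimator):
    """Estimator facade over :func:`build_library`.

    Fitted attributes: ``library_`` and its achieved ``coverage_``.
    """

    def __init__(
        self,
        window=20,
        mcmb: int = 5000,
        target_coverage: float | None = None,
        min_subgroup: int = 0,
    ):
        self.window = window
        self.mcmb = mcmb
        self.target_coverage = target_coverage
        self.min_subgroup = min_subgroup

    def fit(self, gametes: GameteSet, y=None, subgroup_labels=None):
        self.library_ = build_library(
            gametes,
            window=self.window,
            mcmb=self.mcmb,
            target_coverage=self.target_coverage,
            subgroup_labels=subgroup_labels,
            min_subgroup=self.min_subgroup,
        )
        self.coverage_ = self.library_.coverage
        return self
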