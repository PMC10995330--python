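"""Core data containers for phased genotypes.

The universal substrate of the pipeline is a phased gamete matrix: every
individual owns exactly two gametes (rows ``2*i`` and ``2*i + 1``), each a
0/1 vector over the SNPs of a genetic map.  Doubled-haploid (DH) lines carry
two identical gametes; gamete-capture (GC) lines carry two phased,
generally distinct gametes.  Treating the two phased gametes of a GC
individual as two pseudo-inbred haplotypes preserves phase information for
all block-construction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: sentinel allele code for a missing call (only produced at the VCF boundary)
MISSING = 255


@dataclass(frozen=True)
class GeneticMap:
    """Marker map: chromosome, physical (bp, 1-based) and genetic (cM) position.

    Within each chromosome both bp and cM must be strictly increasing and
    chromosomes must form contiguous runs in input order.
    """

    chrom: np.ndarray
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chrom)
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        if not (len(chrom) == len(bp) == len(cm)):
            raise ValueError("map columns must have equal length")
        if len(bp) == 0:
            raise ValueError("empty genetic map")
        if bp.min() < 1:
            raise ValueError("bp positions are 1-based and must be >= 1")
        if cm.min() < 0:
            raise ValueError("cM positions must be >= 0")
        # chromosomes must be contiguous runs
        seen = {}
        order = []
        for c in chrom:
            if c in seen:
                if order[-1] != c:
                    raise ValueError(f"chromosome {c!r} is not a contiguous run")
            else:
                seen[c] = True
                order.append(c)
        for c in order:
            sel = chrom == c
            if np.any(np.diff(bp[sel]) <= 0):
                raise ValueError(f"bp not strictly increasing on chromosome {c!r}")
            # non-decreasing: zero-recombination (0 cM) chromosomes are legal
            if np.any(np.diff(cm[sel]) < 0):
                raise ValueError(f"cM decreasing on chromosome {c!r}")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)

    @property
    def n_snp(self) -> int:
        return len(self.bp)

    @property
    def chromosomes(self) -> list:
        out = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> slice of global SNP indices."""
        out = {}
        for c in self.chromosomes:
            idx = np.flatnonzero(self.chrom == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def subset(self, index: np.ndarray) -> "GeneticMap":
        index = np.asarray(index)
        return GeneticMap(self.chrom[index], self.bp[index], self.cm[index])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"chrom": self.chrom, "bp": self.bp, "cM": self.cm})

    @classmethod
    def from_frame(cls, df) -> "GeneticMap":
        return cls(df["chrom"].to_numpy(), df["bp"].to_numpy(), df["cM"].to_numpy())


def uniform_map(
    n_snp: int, n_chrom: int = 2, cm_per_chrom: float = 150.0, bp_per_cm: int = 1_000_000
) -> GeneticMap:
    """Evenly spaced map: ``n_snp`` markers split across ``n_chrom`` chromosomes."""
    if n_snp < 2:
        raise ValueError("need at least 2 SNPs")
    per = [n_snp // n_chrom + (1 if i < n_snp % n_chrom else 0) for i in range(n_chrom)]
    chrom, bp, cm = [], [], []
    for i, m in enumerate(per):
        if m == 0:
            continue
        pos = np.linspace(0.0, cm_per_chrom, m, endpoint=False)
        chrom += [f"chr{i + 1}"] * m
        cm.append(pos)
        bp.append(np.round(pos * bp_per_cm).astype(np.int64) + 1)
    return GeneticMap(np.array(chrom), np.concatenate(bp), np.concatenate(cm))


@dataclass
class GameteSet:
    """Phased gamete x SNP matrix with map and individual/population labels.

    ``alleles`` has shape (2 * n_individuals, n_snp); rows ``2i`` and
    ``2i + 1`` are the two gametes of ``individuals[i]``.  Entries are 0/1
    (255 marks a missing call, only ever present straight after VCF import).
    ``origins`` optionally tracks per-cell parental origin codes (used by the
    gamete-capture simulator: 0 = landrace, 1 = FV2).
    """

    alleles: np.ndarray
    gmap: GeneticMap
    individuals: np.ndarray
    populations: np.ndarray
    origins: np.ndarray | None = None

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.individuals = np.asarray(self.individuals)
        self.populations = np.asarray(self.populations)
        n_g, m = self.alleles.shape
        if m != self.gmap.n_snp:
            raise ValueError("allele matrix width does not match map")
        if n_g != 2 * len(self.individuals):
            raise ValueError("each individual must own exactly two gamete rows")
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label per individual required")
        if len(np.unique(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids must be unique")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0/1 (or 255 for missing)")
        if self.origins is not None and self.origins.shape != self.alleles.shape:
            raise ValueError("origins must match allele matrix shape")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_gametes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.alleles == MISSING).any())

    def gamete_individuals(self) -> np.ndarray:
        return np.repeat(self.individuals, 2)

    def gamete_populations(self) -> np.ndarray:
        return np.repeat(self.populations, 2)

    def gametes_of(self, individual) -> np.ndarray:
        i = int(np.flatnonzero(self.individuals == individual)[0])
        return np.array([2 * i, 2 * i + 1])

    # -- derived views ---------------------------------------------------
    def dosage(self) -> np.ndarray:
        """Individual x SNP allele-count (0/1/2) matrix."""
        if self.has_missing:
            raise ValueError("cannot form dosages with missing calls present")
        a = self.alleles.astype(np.int16)
        return a[0::2] + a[1::2]

    def is_dh(self) -> np.ndarray:
        """Per-individual flag: both gametes identical (fully homozygous)."""
        return (self.alleles[0::2] == self.alleles[1::2]).all(axis=1)

    # -- subsetting / combination ----------------------------------------
    def subset(self, individuals=None, population=None) -> "GameteSet":
        if (individuals is None) == (population is None):
            raise ValueError("give exactly one of individuals/population")
        if population is not None:
            mask = self.populations == population
            if not mask.any():
                raise ValueError(f"unknown population {population!r}")
            idx = np.flatnonzero(mask)
        else:
            individuals = np.asarray(individuals)
            pos = {ind: i for i, ind in enumerate(self.individuals)}
            missing = [i for i in individuals if i not in pos]
            if missing:
                raise ValueError(f"unknown individuals: {missing[:5]}")
            idx = np.array([pos[i] for i in individuals])
        rows = np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))
        return GameteSet(
            self.alleles[rows],
            self.gmap,
            self.individuals[idx],
            self.populations[idx],
            None if self.origins is None else self.origins[rows],
        )

    def subset_snps(self, index: np.ndarray) -> "GameteSet":
        index = np.asarray(index)
        return GameteSet(
            self.alleles[:, index],
            self.gmap.subset(index),
            self.individuals,
            self.populations,
            None if self.origins is None else self.origins[:, index],
        )

    @staticmethod
    def concat(*sets: "GameteSet") -> "GameteSet":
        """Stack gamete sets sharing one map (e.g. merged TS + PS genotypes)."""
        first = sets[0]
        for s in sets[1:]:
            if s.gmap.n_snp != first.gmap.n_snp or not np.array_equal(s.gmap.bp, first.gmap.bp):
                raise ValueError("gamete sets must share the same map")
        origins = None
        if all(s.origins is not None for s in sets):
            origins = np.vstack([s.origins for s in sets])
        return GameteSet(
            np.vstack([s.alleles for s in sets]),
            first.gmap,
            np.concatenate([s.individuals for s in sets]),
            np.concatenate([s.populations for s in sets]),
            origins,
        )

    def copy(self) -> "GameteSet":
        return replace(
            self,
            alleles=self.alleles.copy(),
            origins=None if self.origins is None else self.origins.copy(),
        )
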