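"""Genotype I/O and quality-control filters.

Reads and writes phased VCF (one diploid sample per individual, ``|``
separated GT), marker-map / phenotype / label CSVs and BED gene tracks, and
applies the array-data QC used for landrace DH and GC panels: drop markers
and individuals with >10% missing calls, for DH material additionally drop
markers and individuals with >5% heterozygosity and set residual
heterozygous calls to missing.  Imputation is deliberately not implemented:
real inputs are assumed already imputed and phased, synthetic inputs are
emitted complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gametes import MISSING, GameteSet, GeneticMap


@dataclass
class RawGenotypes:
    """Individual x SNP call matrix with 0/1/2 dosages and NaN for missing."""

    calls: np.ndarray  # float64, entries in {0, 1, 2, nan}
    gmap: GeneticMap
    individuals: np.ndarray
    populations: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.float64)
        if self.calls.shape != (len(self.individuals), self.gmap.n_snp):
            raise ValueError("call matrix shape inconsistent with ids/map")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("calls must be 0/1/2 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snp(self) -> int:
        return self.calls.shape[1]

    @classmethod
    def from_gametes(cls, gs: GameteSet) -> "RawGenotypes":
        a = gs.alleles.astype(np.float64)
        a[gs.alleles == MISSING] = np.nan
        calls = a[0::2] + a[1::2]  # NaN propagates per-individual
        return cls(calls, gs.gmap, gs.individuals.copy(), gs.populations.copy())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_phased_vcf(gs: GameteSet, path: str) -> None:
    """Plain-text phased VCF; cM positions stored in an INFO ``CM`` field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in gs.gmap.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gs.individuals))
            + "\n"
        )
        a = gs.alleles
        for j in range(gs.n_snp):
            col = a[:, j]
            gts = []
            for i in range(gs.n_individuals):
                x, y = col[2 * i], col[2 * i + 1]
                sx = "." if x == MISSING else str(int(x))
                sy = "." if y == MISSING else str(int(y))
                gts.append(f"{sx}|{sy}")
            fh.write(
                f"{gs.gmap.chrom[j]}\t{gs.gmap.bp[j]}\tsnp{j}\tA\tT\t.\tPASS\t"
                f"CM={gs.gmap.cm[j]:.6f}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_phased_vcf(path: str, populations: dict | None = None) -> GameteSet:
    """Read a phased, biallelic-SNP VCF into a gamete matrix.

    Unphased heterozygous GTs are rejected (phase is the substrate of every
    downstream method); unphased homozygotes are accepted.  Missing calls are
    kept as the missing code for the QC step to handle.  1-based VCF POS is
    preserved in the map; cM is taken from the ``CM`` INFO field when present,
    else bp / 1e6.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.array(vcf.samples)
    cols, chroms, bps, cms = [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic site {v.CHROM}:{v.POS}")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a >= 0 and b >= 0 and a != b and not phased:
                raise ValueError(
                    f"unphased heterozygote for sample {samples[i]} at {v.CHROM}:{v.POS}"
                )
            col[2 * i] = MISSING if a < 0 else a
            col[2 * i + 1] = MISSING if b < 0 else b
        cols.append(col)
        chroms.append(v.CHROM)
        bps.append(v.POS)
        cm = v.INFO.get("CM")
        cms.append(float(cm) if cm is not None else v.POS / 1e6)
    if not cols:
        raise ValueError("empty VCF")
    gmap = GeneticMap(np.array(chroms), np.array(bps), np.array(cms))
    pops = np.array([populations.get(s, "pop0") if populations else "pop0" for s in samples])
    return GameteSet(np.column_stack(cols), gmap, samples, pops)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def qc_filter(
    raw: RawGenotypes, max_missing: float = 0.10, max_het: float = 0.05, dh: bool = False
) -> tuple[RawGenotypes, dict]:
    """Missing-rate and (for DH material) heterozygosity filters.

    Order is fixed and documented because it matters on edge cases:
    (1) markers, then individuals, with missing rate strictly above
    ``max_missing`` are dropped; (2) if ``dh``, markers, then individuals,
    with heterozygosity strictly above ``max_het`` are dropped and remaining
    heterozygous calls are set to missing.  Returns the filtered data plus a
    removal report.
    """
    for t in (max_missing, max_het):
        if not 0 <= t <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    calls = raw.calls.copy()
    marker_ids = np.arange(raw.n_snp)
    ind_idx = np.arange(raw.n_individuals)
    report = {
        "markers_missing": [],
        "individuals_missing": [],
        "markers_het": [],
        "individuals_het": [],
        "het_calls_set_missing": 0,
    }

    miss = np.isnan(calls)
    keep_m = miss.mean(axis=0) <= max_missing
    report["markers_missing"] = marker_ids[~keep_m].tolist()
    calls, marker_ids = calls[:, keep_m], marker_ids[keep_m]
    if calls.shape[1] == 0:
        raise ValueError("all markers removed by missing-rate filter")

    miss = np.isnan(calls)
    keep_i = miss.mean(axis=1) <= max_missing
    report["individuals_missing"] = raw.individuals[ind_idx[~keep_i]].tolist()
    calls, ind_idx = calls[keep_i], ind_idx[keep_i]

    if dh:
        het = calls == 1.0
        obs = ~np.isnan(calls)
        with np.errstate(invalid="ignore"):
            het_m = het.sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
        keep_m = het_m <= max_het
        report["markers_het"] = marker_ids[~keep_m].tolist()
        calls, marker_ids = calls[:, keep_m], marker_ids[keep_m]
        if calls.shape[1] == 0:
            raise ValueError("all markers removed by heterozygosity filter")

        het = calls == 1.0
        obs = ~np.isnan(calls)
        het_i = het.sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
        keep_i = het_i <= max_het
        report["individuals_het"] = raw.individuals[ind_idx[~keep_i]].tolist()
        calls, ind_idx = calls[keep_i], ind_idx[keep_i]

        residual = calls == 1.0
        report["het_calls_set_missing"] = int(residual.sum())
        calls[residual] = np.nan

    out = RawGenotypes(
        calls,
        raw.gmap.subset(marker_ids),
        raw.individuals[ind_idx],
        raw.populations[ind_idx],
    )
    return out, report


def keep_polymorphic(geno):
    """Drop markers with a single observed allele.

    A marker is polymorphic if both alleles are observed among non-missing
    calls — a single carrier of the minor allele is enough (rare-allele
    filtering happens only at the haplotype-allele level downstream).
    Accepts RawGenotypes or a complete GameteSet.
    """
    if isinstance(geno, GameteSet):
        if geno.has_missing:
            raise ValueError("resolve missing calls before polymorphism filtering")
        a = geno.alleles
        keep = (a.min(axis=0) == 0) & (a.max(axis=0) == 1)
        return geno.subset_snps(np.flatnonzero(keep))
    calls = geno.calls
    with np.errstate(invalid="ignore"):
        has_ref = np.nansum(2 - calls, axis=0) > 0
        has_alt = np.nansum(calls, axis=0) > 0
    keep = has_ref & has_alt
    idx = np.flatnonzero(keep)
    return RawGenotypes(calls[:, idx], geno.gmap.subset(idx), geno.individuals, geno.populations)


# ---------------------------------------------------------------------------
# CSV / BED helpers
# ---------------------------------------------------------------------------

def write_map_csv(gmap: GeneticMap, path: str) -> None:
    gmap.to_frame().to_csv(path, index=False)


def read_map_csv(path: str) -> GeneticMap:
    return GeneticMap.from_frame(pd.read_csv(path))


def write_phenotypes_csv(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_labels_csv(gs: GameteSet, path: str) -> None:
    pd.DataFrame({"individual": gs.individuals, "population": gs.populations}).to_csv(
        path, index=False
    )


def read_labels_csv(path: str) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["individual"].astype(str), df["population"].astype(str)))


def write_bed(track: pd.DataFrame, path: str) -> None:
    track[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=["chrom", "start", "end"], usecols=[0, 1, 2])
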