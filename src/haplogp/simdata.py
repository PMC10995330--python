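"""Synthetic landrace-derived populations.

Emulates the study design the pipeline targets: two divergent open-pollinated
maize landraces, from each of which a fully homozygous doubled-haploid (DH)
population is derived directly from heterozygous S0 plants, and a
gamete-capture (GC) population is derived by crossing S0 plants with an
inbred capture line (FV2) and selfing once.  Gametes are simulated with a
first-order Markov linkage-disequilibrium process along each chromosome and
recombined by interference-free (Poisson/Haldane) meiosis.

Phenotypes come from either an additive single-SNP QTL model or a
founder-haplotype QTL model in which effects attach to whole ancestral
haplotype segments — local, non-additive-in-SNPs signal that haplotype-based
relationship matrices can exploit but single-marker ones cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gametes import GameteSet, GeneticMap, uniform_map

__all__ = [
    "QTLModel",
    "additive_qtl_model",
    "founder_qtl_model",
    "sim_founders",
    "sim_capture_line",
    "meiosis",
    "sim_dh_population",
    "sim_gc_population",
    "sim_phenotypes",
    "sim_gene_track",
]


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def sim_founders(
    n_founders_per_landrace: int = 35,
    n_snp: int = 2000,
    gmap: GeneticMap | None = None,
    divergence: float = 0.15,
    ld_decay: float = 1.0,
    landraces: tuple[str, str] = ("KE", "PE"),
    seed: int | None = None,
) -> GameteSet:
    """Two labelled pools of heterozygous founder (S0) plants.

    Allele frequencies per landrace follow a Balding–Nichols draw around a
    shared ancestral frequency with differentiation ``divergence`` (F_ST-like;
    0 means both landraces share identical frequency vectors).  Within a
    chromosome, gametes follow a first-order Markov copy process: the latent
    state of marker j is retained from marker j-1 with probability
    ``exp(-ld_decay * d_cM)``, so adjacent-marker correlation decays with map
    distance at rate ``ld_decay`` (per cM).
    """
    if n_founders_per_landrace < 2:
        raise ValueError("need at least 2 founders per landrace")
    if n_snp < 2:
        raise ValueError("need at least 2 SNPs")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    if ld_decay <= 0:
        raise ValueError("ld_decay must be > 0")
    if gmap is None:
        gmap = uniform_map(n_snp)
    elif gmap.n_snp != n_snp:
        raise ValueError("map length disagrees with n_snp")
    rng = np.random.default_rng(seed)

    anc = rng.uniform(0.1, 0.9, size=n_snp)
    sets = []
    for landrace in landraces:
        if divergence == 0:
            p = anc.copy()
        else:
            a = anc * (1 - divergence) / divergence
            b = (1 - anc) * (1 - divergence) / divergence
            p = np.clip(rng.beta(a, b), 0.01, 0.99)
        alleles = _markov_gametes(rng, p, gmap, 2 * n_founders_per_landrace, ld_decay)
        ids = np.array([f"{landrace}_S0_{i:03d}" for i in range(n_founders_per_landrace)])
        sets.append(
            GameteSet(alleles, gmap, ids, np.full(n_founders_per_landrace, landrace))
        )
    return GameteSet.concat(*sets)


def _markov_gametes(rng, p, gmap, n_gametes, ld_decay):
    """Gametes with per-marker frequency ``p`` and cM-decaying LD."""
    m = len(p)
    alleles = np.empty((n_gametes, m), dtype=np.uint8)
    slices = gmap.chrom_slices()
    for sl in slices.values():
        cm = gmap.cm[sl]
        u = rng.random(n_gametes)
        alleles[:, sl.start] = u < p[sl.start]
        for j in range(sl.start + 1, sl.stop):
            rho = np.exp(-ld_decay * (gmap.cm[j] - gmap.cm[j - 1]))
            fresh = rng.random(n_gametes) >= rho
            u = np.where(fresh, rng.random(n_gametes), u)
            alleles[:, j] = u < p[j]
    return alleles


def sim_capture_line(
    gmap: GeneticMap, freq: float | np.ndarray = 0.5, name: str = "FV2", seed: int | None = None
) -> GameteSet:
    """An inbred capture line: one random homozygous genotype (two equal gametes)."""
    rng = np.random.default_rng(seed)
    g = (rng.random(gmap.n_snp) < freq).astype(np.uint8)
    return GameteSet(np.vstack([g, g]), gmap, np.array([name]), np.array([name]))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _crossover_mask(gmap: GeneticMap, rng) -> np.ndarray:
    """Per-SNP boolean: copy from parent A (True) or parent B (False).

    Crossover counts per chromosome are Poisson(length_cM / 100), positions
    uniform on the cM axis, no interference; the starting parent is fair.
    """
    mask = np.empty(gmap.n_snp, dtype=bool)
    for sl in gmap.chrom_slices().values():
        cm = gmap.cm[sl]
        length = cm[-1] - cm[0]
        n_xo = rng.poisson(length / 100.0) if length > 0 else 0
        start = rng.integers(2)
        if n_xo == 0:
            mask[sl] = start == 0
            continue
        xo = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
        phase = (start + np.searchsorted(xo, cm, side="right")) % 2
        mask[sl] = phase == 0
    return mask


def meiosis(gamete_a: np.ndarray, gamete_b: np.ndarray, gmap: GeneticMap, seed=None) -> np.ndarray:
    """One recombinant gamete from a pair of phased parental gametes."""
    a = np.asarray(gamete_a)
    b = np.asarray(gamete_b)
    if a.shape != (gmap.n_snp,) or b.shape != (gmap.n_snp,):
        raise ValueError("gametes must match map length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _crossover_mask(gmap, rng)
    return np.where(mask, a, b).astype(a.dtype)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def _single_pool(founders: GameteSet) -> str:
    pops = np.unique(founders.populations)
    if len(pops) != 1:
        raise ValueError("founders must come from a single landrace pool")
    return str(pops[0])


def sim_dh_population(
    founders: GameteSet, n_lines: int, seed: int | None = None, name: str | None = None
) -> GameteSet:
    """Doubled-haploid lines, one per meiotic gamete of a random S0 plant.

    The sampled gamete is duplicated, so every line is fully homozygous.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    landrace = _single_pool(founders)
    name = name or f"DH_{landrace}"
    rng = np.random.default_rng(seed)
    m = founders.n_snp
    alleles = np.empty((2 * n_lines, m), dtype=np.uint8)
    for i in range(n_lines):
        f = rng.integers(founders.n_individuals)
        g = meiosis(founders.alleles[2 * f], founders.alleles[2 * f + 1], founders.gmap, rng)
        alleles[2 * i] = g
        alleles[2 * i + 1] = g
    ids = np.array([f"{name}_{i:04d}" for i in range(n_lines)])
    return GameteSet(alleles, founders.gmap, ids, np.full(n_lines, name))


def sim_gc_population(
    founders: GameteSet,
    fv2_gametes: np.ndarray,
    n_lines: int,
    seed: int | None = None,
    name: str | None = None,
) -> GameteSet:
    """Gamete-capture S1 lines from (S0 x FV2) F1 plants, phase preserved.

    Each line: an F1 is formed from one meiotic landrace gamete and the FV2
    gamete; the line's two phased gametes are two independent meioses of that
    F1.  Per-cell parental origin (0 = landrace, 1 = FV2) is tracked in
    ``origins``; its expectation is 50% FV2 genome share.
    """
    fv2_gametes = np.asarray(fv2_gametes, dtype=np.uint8)
    if fv2_gametes.ndim == 2:
        if fv2_gametes.shape[0] != 2 or not np.array_equal(fv2_gametes[0], fv2_gametes[1]):
            raise ValueError("capture line must be inbred (two identical gametes)")
        fv2 = fv2_gametes[0]
    else:
        fv2 = fv2_gametes
    if fv2.shape != (founders.n_snp,):
        raise ValueError("FV2 gamete length must match map")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    landrace = _single_pool(founders)
    name = name or f"GC_{landrace}"
    rng = np.random.default_rng(seed)
    gmap = founders.gmap
    m = founders.n_snp
    alleles = np.empty((2 * n_lines, m), dtype=np.uint8)
    origins = np.empty((2 * n_lines, m), dtype=np.uint8)
    fv2_origin = np.ones(m, dtype=np.uint8)
    for i in range(n_lines):
        f = rng.integers(founders.n_individuals)
        lg = meiosis(founders.alleles[2 * f], founders.alleles[2 * f + 1], gmap, rng)
        lg_origin = np.zeros(m, dtype=np.uint8)
        for k in range(2):  # two S1 gametes of the F1
            mask = _crossover_mask(gmap, rng)
            alleles[2 * i + k] = np.where(mask, lg, fv2)
            origins[2 * i + k] = np.where(mask, lg_origin, fv2_origin)
    ids = np.array([f"{name}_{i:04d}" for i in range(n_lines)])
    return GameteSet(alleles, gmap, ids, np.full(n_lines, name), origins)


# ---------------------------------------------------------------------------
# QTL models and phenotypes
# ---------------------------------------------------------------------------

@dataclass
class QTLModel:
    """Trait architecture.

    ``additive_snp``: ``positions`` are marker indices, ``effects`` their
    additive allele-substitution effects.
    ``founder_haplotype``: ``regions`` are [start, end) marker-index windows
    and ``region_effects[r]`` maps an allele sequence (bytes of the uint8
    slice) to the effect of carrying that ancestral haplotype; sequences not
    in the table (rare within-region recombinants) contribute 0.  When the
    population tracks parental origins (gamete-capture lines) and
    ``fv2_effects`` is set, a region fully inherited from the capture-line
    background contributes ``fv2_effects[r]`` instead of a table lookup —
    capture-line haplotype alleles then carry effects of their own that no
    landrace haplotype predicts.
    """

    mode: str
    positions: np.ndarray | None = None
    effects: np.ndarray | None = None
    regions: list[tuple[int, int]] = field(default_factory=list)
    region_effects: list[dict[bytes, float]] = field(default_factory=list)
    fv2_effects: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("additive_snp", "founder_haplotype"):
            raise ValueError(f"unknown QTL mode {self.mode!r}")
        if self.mode == "additive_snp":
            self.positions = np.asarray(self.positions, dtype=np.int64)
            self.effects = np.asarray(self.effects, dtype=np.float64)
            if len(self.positions) != len(self.effects):
                raise ValueError("one effect per QTL position required")
            if not np.all(np.isfinite(self.effects)):
                raise ValueError("effects must be finite")
        else:
            if len(self.regions) != len(self.region_effects):
                raise ValueError("one effect table per region required")

    def genetic_values(self, population: GameteSet) -> np.ndarray:
        if population.has_missing:
            raise ValueError("population has missing calls")
        if self.mode == "additive_snp":
            if self.positions.max(initial=-1) >= population.n_snp:
                raise ValueError("QTL position outside marker range")
            dose = population.dosage()[:, self.positions]
            return dose @ self.effects
        g = np.zeros(population.n_individuals)
        H = population.alleles
        origins = population.origins
        for r, ((s, e), table) in enumerate(zip(self.regions, self.region_effects)):
            for row in range(population.n_gametes):
                if (
                    self.fv2_effects is not None
                    and origins is not None
                    and origins[row, s:e].all()
                ):
                    g[row // 2] += self.fv2_effects[r]
                    continue
                eff = table.get(H[row, s:e].tobytes())
                if eff is not None:
                    g[row // 2] += eff
        return g


def additive_qtl_model(n_snp: int, n_qtl: int, seed=None, effect_sd: float = 1.0) -> QTLModel:
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(n_snp, size=n_qtl, replace=False))
    return QTLModel("additive_snp", positions=pos, effects=rng.normal(0, effect_sd, n_qtl))


def founder_qtl_model(
    founders: GameteSet,
    n_qtl: int,
    region_size: int = 20,
    seed=None,
    effect_sd: float = 1.0,
    fv2_effect_sd: float = 0.0,
) -> QTLModel:
    """Effects attached to the distinct founder haplotypes of random regions.

    ``fv2_effect_sd > 0`` additionally draws one capture-line background
    effect per region, expressed by gamete-capture lines wherever a region is
    fully FV2-derived (see :class:`QTLModel`).
    """
    rng = np.random.default_rng(seed)
    slices = list(founders.gmap.chrom_slices().values())
    regions, tables = [], []
    for _ in range(n_qtl):
        sl = slices[rng.integers(len(slices))]
        width = min(region_size, sl.stop - sl.start)
        s = int(rng.integers(sl.start, sl.stop - width + 1))
        regions.append((s, s + width))
        seqs = np.unique(founders.alleles[:, s : s + width], axis=0)
        tables.append({seq.tobytes(): float(rng.normal(0, effect_sd)) for seq in seqs})
    fv2_eff = rng.normal(0, fv2_effect_sd, n_qtl) if fv2_effect_sd > 0 else None
    return QTLModel(
        "founder_haplotype", regions=regions, region_effects=tables, fv2_effects=fv2_eff
    )


def sim_phenotypes(
    population: GameteSet,
    qtl_model: QTLModel,
    h2: float,
    seed=None,
    trait: str = "trait",
) -> pd.DataFrame:
    """Phenotypes (stand-ins for trial-adjusted means) at target heritability.

    Residual variance is scaled to the realized genetic variance of the
    sample so that Var(g) / Var(p) = h2 holds in expectation for the sample
    at hand.  Returns a table with columns
    ``individual, trait, value, true_g, h2``.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    g = qtl_model.genetic_values(population)
    var_g = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
    if h2 < 1 and var_g == 0:
        raise ValueError("zero genetic variance: noise scale undefined for h2 < 1")
    e = 0.0 if h2 == 1 else rng.normal(0.0, np.sqrt(var_g * (1 - h2) / h2), len(g))
    return pd.DataFrame(
        {
            "individual": population.individuals,
            "trait": trait,
            "value": g + e,
            "true_g": g,
            "h2": h2,
        }
    )


# ---------------------------------------------------------------------------
# gene annotation track
# ---------------------------------------------------------------------------

def sim_gene_track(gmap: GeneticMap, n_genes: int, seed=None) -> pd.DataFrame:
    """Non-overlapping gene intervals (BED convention: 0-based, half-open)."""
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = gmap.chromosomes
    slices = gmap.chrom_slices()
    lengths = np.array([float(gmap.bp[slices[c].stop - 1]) for c in chroms])
    rows = []
    counts = rng.multinomial(n_genes, lengths / lengths.sum()) if n_genes else []
    for c, k in zip(chroms, counts):
        if k == 0:
            continue
        max_bp = int(gmap.bp[slices[c].stop - 1])
        # 2k sorted distinct breakpoints paired up -> k disjoint intervals
        pts = np.sort(rng.choice(max_bp, size=2 * k, replace=False))
        for i in range(k):
            rows.append((c, int(pts[2 * i]), int(pts[2 * i + 1] + 1)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
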