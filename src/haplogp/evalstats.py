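"""Prediction scenarios, resampling designs and comparison statistics.

Three scenarios organise training set (TS) and prediction set (PS):
within population (1: ten iterations of five-fold cross-validation), across
population type within a landrace (2) and across landraces within a type
(3), the latter two by repeated random sampling of 200 TS and 50 PS lines.
Accuracy is r(predicted, observed phenotype) / sqrt(h2) with the h2 of the
prediction set.  Haplotypes are constructed once per population in scenario
1 and on the merged TS + PS genotypes in scenarios 2/3; in scenario 2 the
capture line FV2 joins the GC subgroup during library construction.

Also implemented: the Mantel test between relationship matrices, the exact
Wilcoxon signed-rank test for paired accuracy comparisons with Bonferroni
correction, and the FV2 haplotype-composition criterion used to tune the
Min-Subgroup parameter without phenotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .gametes import GameteSet
from .gblup import GBLUP, prediction_accuracy
from .hapgrm import GRM, PseudoMarkerMatrix, drop_singletons, encode_alleles, grm_vanraden, snp_grm
from .haplib import HaplotypeLibrary, extend_blocks, filter_mcmb, filter_min_subgroup, window_clusters
from .ldblocks import fixed_blocks, four_gamete_blocks, gabriel_blocks, spine_blocks

__all__ = [
    "GRMMethod",
    "make_method",
    "run_scenario1",
    "run_scenario_across",
    "mantel_test",
    "signed_rank_test",
    "wilcoxon_signed_rank",
    "bonferroni",
    "fv2_composition",
    "tune_min_subgroup",
]


# ---------------------------------------------------------------------------
# method registry: name -> relationship-matrix builder
# ---------------------------------------------------------------------------

@dataclass
class GRMMethod:
    """A named recipe turning a construction GameteSet into a GRM.

    ``build`` constructs haplotypes on the full construction set (which may
    include FV2), encodes pseudo-markers, restricts to the analysis
    individuals, applies the singleton-allele exclusion within that
    population and returns the VanRaden GRM.
    """

    name: str
    kind: str  # snp | fixed | gab | 4gam | spine | haplib
    params: dict = field(default_factory=dict)

    def build(self, construction: GameteSet, analysis_ids=None, subgroup_labels=None) -> GRM:
        if analysis_ids is None:
            analysis_ids = construction.individuals
        analysis_ids = np.asarray(analysis_ids)
        if self.kind == "snp":
            return snp_grm(construction.subset(individuals=analysis_ids))
        if self.kind == "fixed":
            blocks = fixed_blocks(construction.gmap, self.params.get("window_size", 20))
        elif self.kind == "gab":
            blocks = gabriel_blocks(construction, construction.gmap, **self.params)
        elif self.kind == "4gam":
            blocks = four_gamete_blocks(construction, construction.gmap, **self.params)
        elif self.kind == "spine":
            blocks = spine_blocks(construction, construction.gmap, **self.params)
        elif self.kind == "haplib":
            from .haplib import build_library

            params = dict(self.params)
            if params.get("min_subgroup", 0) > 0 and subgroup_labels is None:
                subgroup_labels = construction.gamete_populations()
            blocks = build_library(construction, subgroup_labels=subgroup_labels, **params)
            if blocks.n_blocks == 0:
                raise ValueError(f"method {self.name}: empty haplotype library")
        else:
            raise ValueError(f"unknown method kind {self.kind!r}")
        pmm = encode_alleles(blocks, construction)
        pmm = pmm.subset_individuals(analysis_ids)
        pmm = drop_singletons(pmm)
        if pmm.n_alleles == 0:
            raise ValueError(f"method {self.name}: no alleles left after singleton filter")
        return grm_vanraden(pmm, kind=self.name)


def make_method(spec: str) -> GRMMethod:
    """Parse a method spec string: ``snp``, ``fixed:20``, ``gab``, ``4gam``,
    ``spine`` or ``haplib:window=20,mcmb=5000,min_subgroup=40``."""
    kind, _, rest = spec.partition(":")
    kind = kind.strip().lower()
    params: dict = {}
    if kind == "fixed":
        params["window_size"] = int(rest) if rest else 20
        return GRMMethod(f"FixedHB({params['window_size']})", "fixed", params)
    if rest:
        for item in rest.split(","):
            k, _, v = item.partition("=")
            try:
                val = int(v)
            except ValueError:
                val = float(v)
            params[k.strip()] = val
    names = {"snp": "SNP", "gab": "GAB", "4gam": "4GAM", "spine": "SPINE", "haplib": "haplib"}
    if kind not in names:
        raise ValueError(f"unknown method {spec!r}")
    name = names[kind]
    if kind == "haplib" and rest:
        name = f"haplib({rest})"
    return GRMMethod(name, kind, params)


def _as_methods(methods) -> list[GRMMethod]:
    out = []
    for m in methods:
        out.append(m if isinstance(m, GRMMethod) else make_method(m))
    return out


def _trait_frame(phenotypes: pd.DataFrame, trait: str, ids) -> tuple[np.ndarray, float]:
    sub = phenotypes[phenotypes["trait"] == trait].set_index("individual")
    y = sub.loc[np.asarray(ids), "value"].to_numpy(dtype=float)
    h2 = float(sub["h2"].iloc[0]) if "h2" in sub else 1.0
    return y, h2


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------

def run_scenario1(
    gametes: GameteSet,
    phenotypes: pd.DataFrame,
    methods,
    traits=None,
    k: int = 5,
    iters: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-population k-fold cross-validation, iterated.

    Haplotypes (hence GRMs) are constructed once on the full population;
    fold assignments are shuffled per iteration and shared across methods so
    method comparisons are paired.
    """
    methods = _as_methods(methods)
    n = gametes.n_individuals
    if k > n:
        raise ValueError("more folds than individuals")
    if traits is None:
        traits = list(pd.unique(phenotypes["trait"]))
    grms = {
        m.name: m.build(gametes, subgroup_labels=gametes.gamete_populations()) for m in methods
    }
    rng = np.random.default_rng(seed)
    records = []
    for it in range(iters):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for trait in traits:
            y, h2 = _trait_frame(phenotypes, trait, gametes.individuals)
            for f, fold in enumerate(folds):
                test = np.zeros(n, dtype=bool)
                test[fold] = True
                for m in methods:
                    U = grms[m.name].values
                    est = GBLUP().fit(U[np.ix_(~test, ~test)], y[~test])
                    pred = est.predict(U[np.ix_(test, ~test)])
                    acc = prediction_accuracy(pred, y[test], h2)
                    records.append(
                        {
                            "scenario": 1,
                            "method": m.name,
                            "trait": trait,
                            "iteration": it,
                            "fold": f,
                            "replicate": it * k + f,
                            "accuracy": acc,
                        }
                    )
    return pd.DataFrame(records)


def run_scenario_across(
    pop_ts: GameteSet,
    pheno_ts: pd.DataFrame,
    pop_ps: GameteSet,
    pheno_ps: pd.DataFrame,
    methods,
    scenario: int = 2,
    traits=None,
    n_ts: int = 200,
    n_ps: int = 50,
    reps: int = 100,
    seed: int = 0,
    fv2: GameteSet | None = None,
    fv2_subgroup: str | None = None,
) -> pd.DataFrame:
    """Across-population / across-landrace prediction by repeated sampling.

    Per repeat (seeded substreams, shared across methods): sample ``n_ts``
    TS and ``n_ps`` PS lines without replacement, construct haplotypes on the
    merged TS + PS genotypes, fit on TS, predict PS.  For library methods in
    scenario 2, the capture line ``fv2`` is appended to the GC subgroup for
    construction only (it never enters the GRM or the training set).
    """
    methods = _as_methods(methods)
    if pop_ts.n_individuals < n_ts or pop_ps.n_individuals < n_ps:
        raise ValueError("insufficient lines for the requested TS/PS sizes")
    if traits is None:
        traits = list(pd.unique(pheno_ts["trait"]))
    if fv2 is not None and fv2_subgroup is None:
        gc_pops = [p for p in (pop_ts.populations[0], pop_ps.populations[0]) if str(p).startswith("GC")]
        fv2_subgroup = gc_pops[0] if gc_pops else str(pop_ps.populations[0])
    streams = np.random.SeedSequence(seed).spawn(reps)
    records = []
    for rep in range(reps):
        rng = np.random.default_rng(streams[rep])
        ts_ids = rng.choice(pop_ts.individuals, size=n_ts, replace=False)
        ps_ids = rng.choice(pop_ps.individuals, size=n_ps, replace=False)
        ts = pop_ts.subset(individuals=ts_ids)
        ps = pop_ps.subset(individuals=ps_ids)
        merged = GameteSet.concat(ts, ps)
        analysis_ids = np.concatenate([ts_ids, ps_ids])
        merged_fv2 = None
        for trait in traits:
            y_ts, _ = _trait_frame(pheno_ts, trait, ts_ids)
            y_ps, h2_ps = _trait_frame(pheno_ps, trait, ps_ids)
            for m in methods:
                construction = merged
                labels = merged.gamete_populations()
                if m.kind == "haplib" and fv2 is not None and scenario == 2:
                    if merged_fv2 is None:
                        merged_fv2 = GameteSet.concat(merged, fv2)
                    construction = merged_fv2
                    labels = construction.gamete_populations().copy()
                    labels[labels == fv2.populations[0]] = fv2_subgroup
                U = m.build(construction, analysis_ids=analysis_ids, subgroup_labels=labels)
                tr = np.arange(n_ts)
                pr = np.arange(n_ts, n_ts + n_ps)
                est = GBLUP().fit(U.values[np.ix_(tr, tr)], y_ts)
                pred = est.predict(U.values[np.ix_(pr, tr)])
                records.append(
                    {
                        "scenario": scenario,
                        "method": m.name,
                        "trait": trait,
                        "replicate": rep,
                        "accuracy": prediction_accuracy(pred, y_ps, h2_ps),
                    }
                )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _tri(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j]


def mantel_test(G1, G2, n_perm: int = 999, seed=None, exact: bool = False):
    """Mantel correlation of two relationship matrices.

    r is the Pearson correlation of the c(c-1)/2 strictly-lower-triangle
    entries; significance comes from simultaneous row/column permutation of
    the first matrix (one-sided upper, add-one correction).  ``exact=True``
    enumerates all c! permutations instead of sampling.
    """
    A = G1.values if isinstance(G1, GRM) else np.asarray(G1, dtype=float)
    B = G2.values if isinstance(G2, GRM) else np.asarray(G2, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square with equal dimensions")
    c = A.shape[0]
    if c < 4:
        raise ValueError("Mantel test needs at least 4 individuals")
    a, b = _tri(A), _tri(B)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant off-diagonal entries: correlation undefined")
    r_obs = float(stats.pearsonr(a, b).statistic)
    if exact:
        perms = list(permutations(range(c)))
        count = sum(
            1
            for p in perms
            if stats.pearsonr(_tri(A[np.ix_(p, p)]), b).statistic >= r_obs - 1e-12
        )
        return r_obs, count / len(perms)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(c)
        r = stats.pearsonr(_tri(A[np.ix_(p, p)]), b).statistic
        if r >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank + Bonferroni
# ---------------------------------------------------------------------------

def signed_rank_test(paired_a, paired_b, exact_limit: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (if all are zero, p = 1 by convention).
    For n <= ``exact_limit`` the null distribution of W+ is enumerated
    exactly over the 2^n sign patterns (midranks for ties, via a
    subset-sum count); otherwise a tie-corrected normal approximation is
    used.  Returns (W+, p).
    """
    d = np.asarray(paired_a, dtype=float) - np.asarray(paired_b, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        r2 = np.round(2 * ranks).astype(np.int64)  # doubled midranks are integers
        total = int(r2.sum())
        dp = np.zeros(total + 1)
        dp[0] = 1.0
        for r in r2:
            dp[r:] += dp[:-r].copy() if r > 0 else dp
        dp /= 2.0**n
        w2 = int(round(2 * w_plus))
        cdf = dp[: w2 + 1].sum()
        sf = dp[w2:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
        return w_plus, float(p)
    mn = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie
    z = (w_plus - mn) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided p of the Wilcoxon signed-rank test (see signed_rank_test)."""
    return signed_rank_test(paired_a, paired_b)[1]


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment min(1, p * m); m defaults to the family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# FV2 haplotype composition and Min-Subgroup tuning
# ---------------------------------------------------------------------------

def _fv2_counts(obj, fv2_id, dh_individuals, gametes: GameteSet | None):
    dh_individuals = np.asarray(dh_individuals)
    if isinstance(obj, HaplotypeLibrary):
        if gametes is None:
            raise ValueError("library mode needs the construction GameteSet")
        gam_ind = gametes.gamete_individuals()
        is_fv2 = gam_ind == fv2_id
        if not is_fv2.any():
            raise ValueError(f"{fv2_id!r} not in the construction set")
        is_dh = np.isin(gam_ind, dh_individuals)
        total = obj.n_blocks
        n_fv2 = n_fv2_dh = 0
        for b in obj.blocks:
            if is_fv2[b.carriers].any():
                n_fv2 += 1
                if is_dh[b.carriers].any():
                    n_fv2_dh += 1
        return total, n_fv2, n_fv2_dh
    if isinstance(obj, PseudoMarkerMatrix):
        ids = obj.individuals
        fv2_row = np.flatnonzero(ids == fv2_id)
        if len(fv2_row) != 1:
            raise ValueError(f"{fv2_id!r} not among the encoded individuals")
        dh_rows = np.flatnonzero(np.isin(ids, dh_individuals))
        fv2_has = obj.M[fv2_row[0]] > 0
        dh_has = (obj.M[dh_rows] > 0).any(axis=0)
        return obj.n_alleles, int(fv2_has.sum()), int((fv2_has & dh_has).sum())
    raise TypeError("expected HaplotypeLibrary or PseudoMarkerMatrix")


def fv2_composition(obj, fv2_id, dh_individuals, gametes: GameteSet | None = None) -> float:
    """Share of haplotype alleles carried by FV2 *and* present in the DH lines.

    numerator: alleles carried by FV2 that occur in at least one DH
    individual; denominator: all haplotype alleles in the library.
    """
    total, _, n_fv2_dh = _fv2_counts(obj, fv2_id, dh_individuals, gametes)
    if total == 0:
        raise ValueError("empty haplotype library")
    return n_fv2_dh / total


def tune_min_subgroup(
    gametes: GameteSet,
    subgroup_labels,
    fv2_id,
    dh_individuals,
    candidates=tuple(range(10, 161, 10)),
    mcmb: int = 5000,
    window: int = 20,
) -> tuple[int, pd.DataFrame]:
    """Phenotype-free Min-Subgroup tuning by minimizing FV2 composition.

    Builds one library per candidate threshold (shared seed/extension work)
    under a fixed MCMB, computes the FV2 composition of each, and returns the
    candidate minimizing it (ties to the smallest threshold) together with
    the full sweep table (both FV2 counts are reported so the alternative
    composition reading — all FV2 alleles regardless of DH occurrence — is
    recoverable).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate thresholds")
    seeds = window_clusters(gametes, window)
    base = extend_blocks(seeds, gametes)
    base_lib = HaplotypeLibrary(base, {"window": window})
    rows = []
    for t in candidates:
        lib = filter_min_subgroup(base_lib, subgroup_labels, t, gametes)
        lib = filter_mcmb(lib.blocks, mcmb, gametes, lib.params)
        if lib.n_blocks == 0:
            warnings.warn(f"min_subgroup={t}: empty library, candidate skipped")
            continue
        total, n_fv2, n_fv2_dh = _fv2_counts(lib, fv2_id, dh_individuals, gametes)
        rows.append(
            {
                "min_subgroup": t,
                "n_blocks": total,
                "n_fv2_alleles": n_fv2,
                "n_fv2_in_dh": n_fv2_dh,
                "composition": n_fv2_dh / total,
                "coverage": lib.coverage,
            }
        )
    if not rows:
        raise ValueError("every candidate produced an empty library")
    table = pd.DataFrame(rows)
    best = int(table.sort_values(["composition", "min_subgroup"]).iloc[0]["min_subgroup"])
    return best, table
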