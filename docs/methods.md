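# Methods

This note records the models implemented in `haplogp`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic data can
and cannot show.

## Populations and the gamete substrate

Everything operates on a phased gamete × SNP matrix: each individual owns
exactly two gamete rows, DH lines two identical ones. Treating the two
phased gametes of a heterozygous GC line as two pseudo-inbred haplotypes
keeps double-heterozygote phase available to every block method. A genetic
map (chromosome, bp, cM) accompanies the matrix; bp is strictly increasing
within a chromosome, cM non-decreasing (a 0 cM chromosome is legal and
never recombines).

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any
particular data set:

* **Founders.** Ancestral allele frequencies q ~ U(0.1, 0.9). Each
  landrace draws its frequency vector from a Balding–Nichols
  Beta(q(1−F)/F, (1−q)(1−F)/F) with F = `divergence` (default 0.15;
  F = 0 collapses to identical vectors). Within a chromosome, gametes
  follow a first-order Markov copy process on a latent uniform variable:
  the state is retained between adjacent markers with probability
  exp(−`ld_decay` · ΔcM) (default `ld_decay` = 1 per cM), which preserves
  per-marker frequencies while inducing LD that decays with map distance.
* **Meiosis.** Crossover counts per chromosome ~ Poisson(length/100 cM),
  positions uniform on the cM axis, no interference (Haldane). The same
  crossover-mask machinery recombines allele vectors and parental-origin
  vectors, so GC lines carry exact FV2-origin tracking (expected 50%
  genome share; observed within ±3% at n ≥ 270).
* **Populations.** A DH line is one meiotic gamete of a random S0 founder,
  duplicated. A GC line is produced by crossing a meiotic S0 gamete to the
  (inbred) FV2 gamete and taking two independent meioses of that F1 — the
  phased S1 genotype, which is what enters the analysis.
* **Phenotypes.** Additive-SNP mode sums dosage × effect over QTL markers.
  Founder-haplotype mode attaches i.i.d. effects to the distinct founder
  sequences of random QTL regions (default 20 SNPs); this signal is a
  non-linear function of local SNPs, so haplotype alleles can tag it while
  single markers cannot — the mechanism by which haplotype methods are
  expected to win. Optionally each region carries a separate capture-line
  background effect expressed when a GC gamete's region is fully
  FV2-derived. Residual noise is scaled to the realized genetic variance so
  Var(g)/Var(p) = h² for the sample at hand; tables carry the true genetic
  values and h².
* **Defaults** (35 founders per landrace, 2 chromosomes × 150 cM, 2,000
  SNPs ≈ 6.7 SNP/cM) are desk-scale testing conditions, not estimates of
  any real population. Tests that shrink the SNP count shrink chromosome
  length proportionally: at much sparser density, window-level IBD sharing
  between subgroups disappears for map-geometry reasons unrelated to the
  methods under test.

## Block construction

* **FixedHB** tiles each chromosome with windows of exactly `window_size`
  adjacent SNPs; the final window may be shorter (a short tail block rather
  than discarded SNPs, so partitions always cover every marker). Blocks
  never span chromosomes.
* **Pairwise LD** is computed from direct gamete counts — inputs are phased
  and complete, so no EM is needed. D = p11 − pA·pB; D′ = |D|/Dmax with
  Dmax the extreme attainable |D| on the observed sign given the allele
  frequencies. D′ is undefined (an error) at monomorphic loci.
* **D′ confidence bounds** follow the likelihood procedure of the original
  CI-block method: allele frequencies fixed at observed values, a grid over
  D′ ∈ [0, 1] (step 0.001), multinomial likelihood of the four observed
  counts at each grid point, normalized mass treated as a distribution, and
  the central `mass` interval (default 0.90, i.e. 5th/95th bounds — the
  original procedure's convention, kept although the rule is commonly
  described as a "95% CI"; the mass is a parameter). `mass=0` returns the
  MLE grid point.
* **GAB** calls a pair "strong LD" when CI upper ≥ 0.98 and CI lower
  ≥ 0.70, qualifies an interval when ≥ 95% of all within-interval pairs
  are strong (the published rule; the original tool's "informative-pair"
  bookkeeping is deliberately not reproduced), and accepts qualifying
  intervals greedily longest-first, ties to the leftmost start, skipping
  overlaps. No maximum pair-distance cap is applied by default
  (configurable), unlike the original tool's 500 kb cap.
* **4GAM** marks an adjacency "in LD" when the rarest of its four
  two-locus gamete classes has frequency < 0.01; blocks are maximal runs of
  in-LD adjacencies, isolated SNPs stay unassigned.
* **SPINE** extends a block's right edge while the (first, last) pair of
  the extended block is strong LD by the GAB criterion; intermediate pairs
  are not consulted.

CI-based calls sharpen with gamete count, so GAB/SPINE boundaries are
sample-size dependent (as in the original tools); frequency-based
quantities (D′ itself, 4GAM boundaries) are invariant under duplicating
every gamete.

## Haplotype library (IBD-based)

A deliberate simplification of the HaploBlocker idea that preserves exactly
the four parameter semantics the analysis varies:

1. **Seeding**: gametes grouped by identical sequence within consecutive
   windows of `window` SNPs (default 20; multi-window mode pools seeds over
   {5, 10, 20, 50} and deduplicates).
2. **Extension**: each seed grows left/right one SNP at a time while *all*
   carriers agree (exact matching; `merging_error` must be 0 — the
   high-accuracy-array setting — and anything else is rejected). Carriers
   are then recomputed as all gametes matching the extended sequence;
   duplicates collapse and blocks nested inside a strictly longer block
   with identical carriers are dropped.
3. **Min Subgroup**: keep blocks with ≥ threshold carriers in *every*
   predefined subgroup (threshold 0 = identity). When FV2 participates in
   scenario-2 construction it is labelled into the GC subgroup.
4. **MCMB**: keep blocks with cells = (SNP length × carrier count) ≥
   MCMB (default 5000). Coverage — the fraction of gamete × SNP cells
   under at least one kept block — is non-increasing in both MCMB and the
   Min-Subgroup threshold.
5. **Target coverage**: instead of a fixed MCMB, bisect over the sorted
   distinct cell counts for the largest threshold whose coverage still
   meets the target (deterministic, exact on the finite set); if even
   threshold 1 falls short, the full library is returned flagged
   `target_unreachable`.

No claim of equivalence with the original R implementation's graph
simplification and block-rating heuristics is made — only the parameter
behaviour needed here.

## Pseudo-markers and relationship matrices

Partition methods yield one column per distinct observed allele sequence
per block (per-locus row sums are exactly 2); library blocks yield one
column each with the count of the individual's gametes among the carriers
(blocks may overlap, so no row-sum constraint). Alleles carried by exactly
one individual of the analysis population are dropped; FV2 is not an
analysis individual, so by default it does not count toward this singleton
rule in scenario-2 construction sets (the carrier-count population is a
parameter, so the alternative reading is available).

GRMs use VanRaden method 1 with observed allele frequencies of the analysis
set (no base-population frequencies are available or assumed). Monomorphic
columns center to zero and are excluded from the denominator. The weighted
variant G = ZWZᵀ / (2 Σ wⱼpⱼ(1−pⱼ)) normalizes weights to mean 1 so equal
weights reduce exactly to the unweighted GRM; cM-length weights floor
zero-length spans at the smallest positive observed span. With window-1
fixed blocks and no singleton drop, the haplotype GRM equals the SNP GRM to
machine precision (each SNP contributes centered columns z and −z,
doubling numerator and denominator) — asserted at 1e−10 in the tests.

## GBLUP / REML

The restricted likelihood of y = 1μ + u + e is profiled over
λ = σ²e/σ²g using one eigendecomposition of the training kernel; a coarse
121-point grid on log λ ∈ [log 1e−6, log 1e6] brackets the optimum, then
bounded scalar minimization refines it to 1e−8. μ̂ is the GLS mean at λ̂,
and BLUPs propagate to unphenotyped individuals as
û = U[:, train](U_tt + λ̂I)⁻¹(y − 1μ̂). Kernels whose smallest eigenvalue
is barely negative (≥ −1e−8 × mean diagonal) get diagonal jitter; anything
worse is rejected. Degenerate phenotypes (zero variance) and training sets
under 10 lines are rejected.

Correctness anchors: û equals ridge-regression marker BLUPs whenever the
kernel is an inner-product of the dosage matrix (checked to 1e−8), and
(μ̂, û) solve Henderson's mixed-model equations on invertible kernels.
λ̂ is equivariant under kernel scaling, leaving predictions unchanged.

One scale caveat: the variance ratio σ̂²g/(σ̂²g+σ̂²e) estimates the
heritability on the GRM's own scale. For fully inbred DH panels the
VanRaden diagonal is ≈ 2, so the raw ratio estimates h²/(2−h²); recovery
checks therefore use a Hardy–Weinberg (founder) population, where the
diagonal is ≈ 1 and the ratio is unbiased for h².

## Scenarios and statistics

Scenario 1 runs iterated k-fold CV (default 10 × 5-fold) with haplotypes
constructed once per population; fold assignments come from the seeded
shuffle and are shared across methods, making comparisons paired. Scenarios
2/3 resample training and prediction sets (defaults 200/50, 100 repeats)
with per-repeat seed substreams shared across methods; haplotypes are
rebuilt per repeat on the merged TS + PS genotypes. Accuracy divides the
Pearson correlation by √h² of the prediction set (the generator's true h²
in synthetic runs; user-supplied for real data).

The Mantel statistic is the Pearson correlation of strictly-lower-triangle
entries; significance is one-sided upper via simultaneous row/column
permutation of the first matrix with add-one correction (999 permutations
by default; exact enumeration available and used as the test oracle at
c ≤ 5). The Wilcoxon signed-rank test drops zero differences (all-zero →
p = 1 by convention), enumerates the exact null of W⁺ by a subset-sum
count over doubled midranks for n ≤ 25, and uses a tie-corrected normal
approximation (no continuity correction) beyond. Bonferroni adjustment is
min(1, p·m) with the family defaulting to all comparisons in one scenario
batch (the natural grouping; any m can be passed).

FV2 composition is the share of library alleles that FV2 carries *and*
that occur in at least one DH individual, out of all library alleles; the
sweep table also reports the count of all FV2-carried alleles so the
alternative reading (regardless of DH occurrence) is recoverable. The
tuner minimizes composition over candidate Min-Subgroup thresholds at fixed
MCMB, ties to the smallest threshold, skipping candidates that empty the
library.

## QC filters

Order is fixed and documented because it changes results on edge cases:
(1) markers, then individuals, with missing rate strictly > 10% are
dropped; (2) for DH material, markers, then individuals, with
heterozygosity strictly > 5% are dropped, and remaining heterozygous calls
become missing. The filter is idempotent and its removal report accounts
exactly for the dimension changes. A consequence of marker-first ordering
at small n: with fewer than ~20 individuals, any single heterozygous call
already pushes a marker over 5%, so the individual-level filter only
engages in larger panels. Imputation is out of scope: analysis modules
reject missing data, and real inputs are expected pre-imputed and phased.
Polymorphism filtering keeps any marker with both alleles observed — a
single carrier suffices; rare-variant exclusion happens only at the
haplotype-allele level.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
desk scale — typically 10–35 founders per landrace, 200–600 SNPs at the
default marker density, 50–400 lines, 2–10 CV iterations or repeats —
sizes chosen so the full pipeline (including the O(m²)-pair CI
computations of the LD methods) completes in seconds per configuration
while leaving every contract observable. Passing tests demonstrate the
algorithms' contracts and the documented statistical behaviour on data
with this generative structure; they do not certify accuracy levels on
real landrace panels, which depend on LD, phase quality and trait
architecture the generator only stylizes.

## Known limitations

* No crossover interference, selection, genotyping error or multi-trait /
  multi-environment structure in the simulator.
* Exact-match library extension only (merging error 0); no error-tolerant
  merging, SNP recoding or extended-library outputs.
* GBLUP has a single intercept and a single kernel — no multi-kernel,
  dominance/epistasis, or Bayesian alternatives.
* The scenario-2 benefit of Min-Subgroup filtering reported for real
  landrace panels is not reproduced by this generator: with a linear GBLUP,
  population-specific pseudo-marker columns mostly shift predictions
  within the prediction set, and at desk scale the filter's coverage cost
  dominates. The package provides the machinery (filters, composition
  tuning, paired scenarios) rather than a synthetic demonstration of that
  empirical finding.
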