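# Methods

## Filtering cascade

Sites are biallelic SNPs throughout; multiallelic and non-SNP records
are dropped at read time. The cascade removes a site iff its missing
fraction exceeds 0.5 **or** its QUAL is strictly below 30 (both
thresholds strict in the direction of removal; absent QUAL passes),
then applies a Hardy–Weinberg exact test within each population and
drops a site whose p-value falls below α = 10⁻⁶ in *any* population.
The HWE test is the standard two-sided exact test on genotype counts at
fixed allele counts, computed by the stable probability-ratio
recurrence; the conservative any-population rule and the loose α are
chosen to remove only gross genotyping artifacts, not weak structure.
LD pruning is a greedy windowed scan: windows of 50 kb starting at
every `step_sites`-th retained site, removal of the later member of any
pair with dosage-correlation r² > 0.5, passes repeated to a fixed
point, so the retained panel provably contains no within-window pair
above the threshold regardless of step granularity. r² uses
pairwise-complete observations and treats zero-variance columns as
unlinked. VCF coordinates are 1-based inclusive; BED masks are 0-based
half-open and converted at the boundary.

## Diversity statistics

π is accumulated per site as 2c(m−c)/(m(m−1)) with m the callable
chromosomes at the site (so it adapts to missingness); θ_W is
S/(a_{n−1}·L) with a single nominal haploid size n (2 × diploid count
by default) — the two agree with the spectrum-based recomputation
exactly on fully called data, and that equality is a standing test.
Tajima's D uses the full 1989 variance normalization (a₁, a₂, b₁, b₂,
c₁, c₂, e₁, e₂) and is defined as 0 when its numerator vanishes. All
estimators here use called genotypes, not genotype likelihoods: the
synthetic data are clean called genotypes, and at that point the
likelihood machinery of low-coverage pipelines adds nothing. Note that
per-site scaling divides by the number of sites *in the matrix*; when a
matrix holds only variant sites (as simulator output does), the caller
supplies the true callable length at the conversion step instead.

The folded SFS projects each site hypergeometrically to a common
haploid size n; sites with fewer callable chromosomes than the
projection are dropped (no imputation). Class 0 stores monomorphic mass
and is excluded from S. The joint spectrum folds cell (i, j) with
(n₁−i, n₂−j), keeping the orientation with the smaller total count and
breaking exact ties toward the lexicographically smaller index pair;
folding is linear, which the block bootstrap exploits by summing
per-block grids.

F_st is the Weir & Cockerham (1984) weighted estimator: per-site
variance components a (among populations), b (among individuals), c
(within individuals) summed over sites, ratio Σa/Σ(a+b+c). Per-site
sample sizes adapt to missingness. With no polymorphic site the ratio
is undefined and the function raises rather than returning a
placeholder. Finite-sample behavior worth knowing: for byte-identical
samples the realized a component is slightly *negative* (the estimator
subtracts expected sampling variance), so near-zero differentiation can
legitimately produce small negative F_st, as field tools also report.

## Admixture statistics

f3(T; B, C) averages (p̂_T − p̂_B)(p̂_T − p̂_C) − p̂_T(1 − p̂_T)/(n_T − 1)
over sites (n_T = called target chromosomes); the correction removes
the upward bias from sampling noise in p̂_T, making the statistic's
expectation the true f3. Standard errors come from a delete-one
jackknife over consecutive blocks of 500 SNPs (block size exposed;
fewer than two blocks flags the SE as unavailable). Note the corrected
statistic is negative *in expectation* only for genuinely admixed
targets; a single realization where p̂_T happens to equal the reference
frequencies still subtracts the bias term, so the per-dataset zero
reference point is statistical, not algebraic.

Weighted LD: for each SNP pair the target's two-locus covariance
(haplotype covariance when phased data are available, half the genotype
covariance otherwise) is multiplied by reference weights — (p̂_ref1 −
p̂_ref2) at both loci in two-reference mode, (p̂_T − p̂_ref) in
one-reference mode — and binned by genetic distance (default 0.05-cM
bins over 0.5–30 cM; the fit starts at 0.5 cM so the short-range LD of
the source panels themselves, which dies off within ~1/(2N) Morgans,
does not contaminate the admixture signal). The curve is fitted by
least squares as amp·exp(−g·d) + affine with d in Morgans, initialized
from a decay-rate grid with the linear parameters profiled out, then
refined by Levenberg–Marquardt. Uncertainty is a delete-one jackknife
over 20 contiguous site blocks (dropping every pair touching the
block). The fit reports `failure` when the optimizer does not converge
or the amplitude is not distinguishable from zero (|z| < 2): a flat
curve carries no date. The date in years is g × generation time
(default 1 year). LD dating is intended to run on *unpruned* input —
pruning by r² removes exactly the signal being measured.

## Divergence models

The model family is an ancestral population of size N_anc splitting T
diffusion time units ago (1 unit = 2·N_anc generations) into
descendants of relative sizes ν₁, ν₂, optionally with continuous scaled
migration m₁₂ = 2·N_anc·m (fraction of population 1 replaced by
migrants from population 2 per generation) and m₂₁. Families:
`no_migration` (3 parameters), `unidirectional` (+m₁₂),
`bidirectional` (+m₂₁).

**Expected spectra.** The expected folded joint SFS is computed by
Monte-Carlo coalescent: branch-length frequency spectra averaged over a
fixed set of independent genealogies simulated with msprime at a
reference size N_ref, normalized so entries scale linearly with
θ = 4·N_anc·μ·L. The engine uses haploid lineages, for which msprime's
pairwise coalescence time in a population of size s is s generations;
N_ref therefore represents one diffusion unit directly, times enter as
T·N_ref generations, and the branch spectrum is divided by 2·N_ref.
Engine noise is handled by common random numbers: a fixed engine seed
makes the likelihood surface deterministic, and — critically — the
demography passed to the simulator always contains both migration
entries, floored at a vanishing rate (10⁻⁸, never realized), so every
family presents the *same event structure* to the simulator and the
common-random-number property holds across nested families, not just
within one. Without that alignment, composite log-likelihoods from
different families differ by Monte-Carlo noise far exceeding the
χ² scale of a likelihood-ratio test.

**Likelihood.** Poisson composite likelihood over unmasked cells (the
two monomorphic corners are masked), with the scaling θ profiled out in
closed form (θ̂ = Σobs/Σexp). Expected cells at exactly zero under
observed mass are floored at 10⁻⁶ on the unit-θ scale — below the
resolution of the Monte-Carlo engine, so a floored cell reads as
"rarer than measurable" rather than impossible; a hard floor near
machine zero makes the surface unusable at desk-scale genealogy counts.

**Optimization.** A seeded genetic algorithm in log-parameter space
(default population 20, 25 generations, tournament-3 selection, blend
crossover, Gaussian mutation with decaying scale, elitism 2) followed
by Nelder–Mead refinement; `method="local"` skips the GA for
warm-started refits. Bounds: ν ∈ [0.05, 20], T ∈ [10⁻³, 5],
m ∈ [10⁻⁴, 10]; a calendar-time cap on the divergence time (e.g. 7,500
years) is enforced as a penalty through the θ̂-implied unit conversion,
since T in years depends on the fitted θ. Optima on a bound are
flagged. Identical seeds give identical results.

**Model comparison.** Nested families are compared by
2·Δloglik ~ χ²(df = added parameters), clamped at zero. Protocol: fit
both families with the *same* engine settings and warm-start the
richer family from the null optimum — the statistic is then a true
nested-optimization gain on one common Monte-Carlo surface. The plain
χ² reference is used even though migration sits on a boundary (the
50:50 mixture correction would be conservative); measured at the
default settings the false-rejection rate is at or below nominal.
Uncertainty on parameters comes from block-bootstrap pseudo-replicates
(non-overlapping 10-kb blocks resampled with replacement; per-block
folded grids summed per replicate; refits start from the MLE), in
place of information-matrix approximations.

**Conversion.** N_anc = θ̂/(4μL); N_i = ν_i·N_anc;
T_years = 2·N_anc·T·generation-time; per-generation migration fraction
m/(2·N_anc). Defaults μ = 4 × 10⁻⁹ per site per generation and one
generation per year, appropriate for house mice.

## Synthetic data

Two engines, one config. `simulate_split` draws independent
non-recombining loci (default 1 kb) under the configured demography —
star-like splits from a common ancestor with per-population split
times, continuous migration, step size changes (bottlenecks), and an
optional admixture pulse — with binary mutations at rate μ, and lays
loci end to end on one synthetic chromosome (positions are bookkeeping;
loci are independent, and 10-kb bootstrap blocks then span 10 loci).
`simulate_admixture_mosaic` simulates two source haplotype panels on a
recombining 10-Mb chromosome and builds each admixed haplotype as a
mosaic: breakpoints form a Poisson process of rate g per Morgan (g =
pulse age), each segment copies a random panel haplotype from source 1
with the pulse probability, else source 2. Segment lengths are thus
exponential with mean 1/g Morgan and the ancestry covariance between
loci decays as exp(−g·d), which is exactly the signal the weighted-LD
dating estimates; reference individuals and the copying pool are
disjoint haplotypes. Markers are thinned to a configured count (default
900, evenly spaced) to keep the all-pairs LD computation quadratic in a
small number.

Desk-scale defaults: effective sizes ~10³, a few thousand loci, θ
preserved through μ, so every pipeline runs in minutes on one CPU.
What the generator does **not** emulate: sequencing error, exome
capture bias (beyond an optional BED mask hook), genotype-likelihood
uncertainty, selection, and within-locus recombination in split mode.
Passing tests therefore validate the estimators and inference machinery
on clean genotypes, not robustness to low-coverage artifacts.

## Problem sizes used in validation

Recovery checks fit 8+8-sample spectra from 2000 loci with a
200-genealogy engine (GA 16×18 + simplex); LRT error rates use
6+6-sample spectra from 1000 loci with a 400-genealogy engine and
warm-started local refits; dating uses 20 mosaic seeds at g = 50.
These sizes were chosen so the full suite stays desk-scale while each
check retains clear statistical resolution (e.g. LRT power at the
configured gene-flow strength 2Nm = 5 is effectively 1, and the H0
statistic stays inside the χ² envelope at 400 genealogies — at 200 the
across-family engine noise begins to leak into the statistic).

## Known limitations

- The Monte-Carlo expected-SFS engine trades bias for speed: at a few
  hundred genealogies a mild downward bias in fitted T (order 10%) is
  visible; a deterministic moments-style recursion is the natural
  extension point.
- The composite likelihood ignores linkage between SNPs within a locus;
  block-level resampling (bootstrap/jackknife) is the only concession
  to non-independence, as is standard for SFS inference.
- LD dating assumes a single pulse; continuous or multi-wave admixture
  biases g toward an average of the mixing times.
- Genotype-based weighted LD (unphased mode) uses half the genotype
  covariance as the haplotype-LD surrogate, which assumes random mating
  in the target.
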