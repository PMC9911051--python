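# popsplit

Population-genetic analysis of recent colonization and admixture
histories from exome-scale SNP panels, built around the question of how
a commensal species (the motivating case is the Western European house
mouse, *Mus musculus domesticus*, introduced to eastern North America)
spread with human migration: did founding populations pass through a
bottleneck, are any of them admixed from multiple sources, and when did
they diverge?

The package provides, as a library plus a thin CLI:

- **Variant I/O and filtering** — VCF in/out, missingness/QUAL
  thresholds, a per-population exact Hardy–Weinberg outlier test, and
  greedy windowed LD pruning (r² on genotype dosage).
- **Summary statistics** — folded site frequency spectra (1-D and joint
  2-D, with hypergeometric projection), nucleotide diversity π,
  Watterson's θ_W, Tajima's D, and Weir–Cockerham weighted F_st from
  summed variance components.
- **Admixture detection and dating** — the three-population statistic
  f3(T; B, C) = E[(p_T − p_B)(p_T − p_C)] with finite-sample bias
  correction and block-jackknife errors (significantly negative values
  indicate T is admixed), and allele-frequency-difference–weighted LD,
  which decays as `amp·exp(−g·d) + affine` in genetic distance d
  (Morgans), with the decay rate g read as generations since admixture.
- **Demographic inference** — two-population isolation(-with-migration)
  models fitted to the folded joint SFS by Poisson composite likelihood.
  Parameters are diffusion-scaled (ν₁, ν₂ relative to N_anc; T in units
  of 2·N_anc generations; migration as 2·N_anc·m) and converted to real
  units through θ = 4·N_anc·μ·L. Optimization is a seeded genetic
  algorithm in log-parameter space plus Nelder–Mead refinement; nested
  families are compared by likelihood-ratio test; uncertainty comes from
  10-kb block-bootstrap pseudo-replicates.
- **Synthetic data** — an msprime-based coalescent generator for split /
  migration / admixture-pulse demographies, and a recombination-bearing
  mosaic generator whose admixed haplotypes carry the exponential
  ancestry-LD decay used for dating.

## Worked example

Simulate a two-population split (N_anc = 1000, descendant sizes 1200 and
700, split 1000 generations ago, 2000 independent 1-kb loci at
μ = 10⁻⁷), then fit a no-migration divergence model to the folded joint
SFS:

```python
import popsplit as ps

cfg = ps.SimConfig(populations={"EUR": 8, "ENA": 8}, N_anc=1000,
                   N={"EUR": 1200, "ENA": 700}, split_times=1000.0,
                   mu=1e-7, n_loci=2000, seed=101)
gm, popmap = ps.simulate_split(cfg)
obs = ps.joint_folded_sfs(gm, popmap, "EUR", "ENA", 8, 8)
fit = ps.fit_split_model(obs, "no_migration", seed=1)
conv = ps.convert_units(fit, mu=1e-7, L=2_000_000)
print(f"nu1={fit.model.nu1:.2f} nu2={fit.model.nu2:.2f} T={fit.model.T:.3f}")
print(f"N_anc={conv['N_anc']:.0f}  T_years={conv['T_years']:.0f}")
```

```
nu1=1.18 nu2=0.70 T=0.491
N_anc=995  T_years=978
```

The fitted relative sizes and split time sit close to the simulated
truth (ν₁ = 1.2, ν₂ = 0.7, T = 0.5, i.e. 1000 generations): the split
time converts to ~980 years at one generation per year, within the
Monte-Carlo scatter of a single seed.

The same operations are available from the shell:

```sh
popsplit simulate --pops EUR=8,ENA=8 --t-split 1000 --seed 101 \
    --vcf-out sim.vcf --popmap-out sim.popmap
popsplit fst sim.vcf sim.popmap EUR ENA
popsplit fit sim.vcf sim.popmap EUR ENA --family no_migration --seed 1
popsplit report config.yaml   # full filter → stats → f3 → fit bundle
```

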