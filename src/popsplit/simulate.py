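"""Coalescent synthetic data.

Two engines under one config schema:

* :func:`simulate_split` — independent non-recombining loci under a
  demography of populations splitting from a common ancestor, with
  optional continuous migration, population-size changes (bottlenecks)
  and a recent admixture pulse.  Returns called genotypes suitable for
  SFS-based statistics.
* :func:`simulate_admixture_mosaic` — a recombination-bearing chromosome
  where admixed haplotypes are built as mosaics of two source panels with
  Poisson breakpoints, producing the exponentially decaying
  ancestry-weighted LD signal used for admixture dating.

Defaults are desk-scale: effective sizes around 10^3 and a few thousand
1-kb loci, with theta preserved through the mutation rate, so full
pipelines run in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PopulationMap, write_popmap
from .variant_io import write_genetic_map, write_vcf


@dataclass
class SimConfig:
    """Full specification of a synthetic demography.

    ``populations`` maps labels to diploid sample sizes.  ``split_times``
    gives, per population, the time (generations ago) at which it merges
    into the ancestor; a single float applies to all.  ``migration`` maps
    (A, B) to the per-generation fraction of population A replaced by
    migrants from B.  ``admixture_pulse`` is (target, source1, source2,
    proportion_from_source1, generations_ago).  ``size_changes`` lists
    (population, time, past_size) step changes, e.g. a founder bottleneck.
    """

    populations: dict[str, int]
    N_anc: float = 1000.0
    N: dict[str, float] = field(default_factory=dict)
    split_times: dict[str, float] | float = 1000.0
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    admixture_pulse: tuple[str, str, str, float, float] | None = None
    size_changes: list[tuple[str, float, float]] = field(default_factory=list)
    mu: float = 1e-7
    locus_bp: int = 1000
    n_loci: int = 2000
    recombination_morgans: float = 1.0
    mosaic_sites: int = 1000
    seed: int = 1

    def size_of(self, pop: str) -> float:
        return self.N.get(pop, self.N_anc)

    def split_time_of(self, pop: str) -> float:
        if isinstance(self.split_times, dict):
            return self.split_times[pop]
        return float(self.split_times)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for pop, n in self.populations.items():
            if n < 1:
                raise ValueError(f"population {pop!r} needs >= 1 sample")
        if self.admixture_pulse is not None:
            target, s1, s2, prop, g = self.admixture_pulse
            if not 0 < prop < 1:
                raise ValueError("admixture proportion must be in (0, 1)")
            for src in (s1, s2):
                if src not in self.populations:
                    raise ValueError(f"pulse source {src!r} not among populations")
                if g >= self.split_time_of(src):
                    raise ValueError("admixture pulse older than source split time")


def _build_demography(config: SimConfig) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="ANC", initial_size=config.N_anc)
    pulse = config.admixture_pulse
    pulse_target = pulse[0] if pulse else None
    for pop in config.populations:
        dem.add_population(name=pop, initial_size=config.size_of(pop))
    events: list[tuple[float, str, tuple]] = []
    # group plain splits by time so each event merges all same-time derived pops
    by_time: dict[float, list[str]] = {}
    for pop in config.populations:
        if pop == pulse_target:
            continue
        by_time.setdefault(config.split_time_of(pop), []).append(pop)
    for t, derived in by_time.items():
        events.append((t, "split", (derived,)))
    if pulse is not None:
        target, s1, s2, prop, g = pulse
        events.append((g, "admixture", (target, s1, s2, prop)))
    for pop, t, size in config.size_changes:
        events.append((t, "resize", (pop, size)))
    for t, kind, args in sorted(events, key=lambda e: (e[0], e[1])):
        if kind == "split":
            dem.add_population_split(time=t, derived=args[0], ancestral="ANC")
        elif kind == "admixture":
            target, s1, s2, prop = args
            dem.add_admixture(
                time=t, derived=target, ancestral=[s1, s2], proportions=[prop, 1 - prop]
            )
        else:
            dem.add_population_parameters_change(
                time=t, population=args[0], initial_size=args[1]
            )
    for (a, b), m in config.migration.items():
        # forward fraction of a replaced by migrants from b
        dem.set_migration_rate(source=a, dest=b, rate=m)
    dem.sort_events()
    return dem


def simulate_split(
    config: SimConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Simulate independent loci and return diploid genotypes + popmap.

    Loci are laid end to end on one synthetic chromosome (positions are
    bookkeeping only; loci are statistically independent).  Biallelic
    sites only; deterministic per seed.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    dem = _build_demography(config)
    samples = {pop: n for pop, n in config.populations.items()}
    sample_names: list[str] = []
    pop_of: dict[str, str] = {}
    for pop, n in config.populations.items():
        for i in range(n):
            name = f"{pop}_{i}"
            sample_names.append(name)
            pop_of[name] = pop
    rng = np.random.default_rng(seed)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seeds = rng.integers(1, 2**31 - 1, size=config.n_loci)
    positions: list[int] = []
    rows: list[np.ndarray] = []
    replicates = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=config.locus_bp,
        discrete_genome=True,
        num_replicates=config.n_loci,
        random_seed=anc_seed,
    )
    for locus, ts in enumerate(replicates):
        mts = msprime.sim_mutations(
            ts,
            rate=config.mu,
            model=msprime.BinaryMutationModel(),
            random_seed=int(mut_seeds[locus]),
        )
        offset = locus * config.locus_bp
        for var in mts.variants():
            if len(var.alleles) != 2:
                continue
            hap = var.genotypes  # haploid 0/1 calls, sample-ordered
            dosage = hap[0::2] + hap[1::2]
            rows.append(dosage.astype(np.int8))
            positions.append(offset + int(var.site.position) + 1)
    n_sites = len(rows)
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(sample_names)), dtype=np.int8)
    )
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
            "qual": [100.0] * n_sites,
        }
    )
    gm = GenotypeMatrix(samples=sample_names, sites=sites, calls=calls)
    return gm, PopulationMap(pop_of)


@dataclass
class MosaicDataset:
    """Phased mosaic haplotypes plus everything needed for LD dating."""

    gm: GenotypeMatrix
    popmap: PopulationMap
    genetic_map: pd.DataFrame
    haplotypes: dict[str, np.ndarray]  # pop -> (n_sites, n_haplotypes) 0/1
    block_lengths_morgans: np.ndarray
    ancestry_fraction: float
    target: str


def simulate_admixture_mosaic(config: SimConfig, seed: int | None = None) -> MosaicDataset:
    """Build admixed haplotypes as mosaics of two simulated source panels.

    Source panels come from a two-population split simulated with
    recombination on a single chromosome.  Each admixed haplotype is a
    mosaic whose breakpoints form a Poisson process of rate g per Morgan
    (g = pulse age in generations); each segment copies a random source-1
    panel haplotype with probability equal to the pulse proportion, else a
    source-2 haplotype.  Ancestry-block (segment) lengths are therefore
    exponential with mean 1/g Morgans.
    """
    config.validate()
    if config.admixture_pulse is None:
        raise ValueError("mosaic mode requires an admixture_pulse")
    if config.recombination_morgans <= 0:
        raise ValueError("mosaic mode requires recombination > 0")
    seed = config.seed if seed is None else seed
    target, s1, s2, prop, g = config.admixture_pulse
    n_target_dip = config.populations[target]
    n_ref_dip = {p: config.populations[p] for p in (s1, s2)}
    n_pool = 40  # copying panel haplotypes per source, separate from refs
    chrom_bp = 10_000_000
    morgans = config.recombination_morgans
    recomb_rate = morgans / chrom_bp

    # ploidy=1 haplotype panels: initial_size 2N gives the diploid-N
    # pairwise coalescent time of 2N generations
    dem = msprime.Demography()
    dem.add_population(name="ANC", initial_size=2 * config.N_anc)
    dem.add_population(name=s1, initial_size=2 * config.size_of(s1))
    dem.add_population(name=s2, initial_size=2 * config.size_of(s2))
    dem.add_population_split(
        time=min(config.split_time_of(s1), config.split_time_of(s2)),
        derived=[s1, s2],
        ancestral="ANC",
    )
    rng = np.random.default_rng(seed)
    n_hap_src = {
        s1: 2 * n_ref_dip[s1] + n_pool,
        s2: 2 * n_ref_dip[s2] + n_pool,
    }
    ts = msprime.sim_ancestry(
        samples={s1: n_hap_src[s1], s2: n_hap_src[s2]},
        ploidy=1,
        demography=dem,
        sequence_length=chrom_bp,
        recombination_rate=recomb_rate,
        discrete_genome=True,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=config.mu,
        model=msprime.BinaryMutationModel(),
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    pos_list: list[int] = []
    hap_rows: list[np.ndarray] = []
    for var in mts.variants():
        if len(var.alleles) != 2:
            continue
        pos_list.append(int(var.site.position) + 1)
        hap_rows.append(var.genotypes.astype(np.int8))
    haps_all = np.array(hap_rows, dtype=np.int8)  # (S, total haplotypes)
    pos = np.array(pos_list)
    # thin to the configured marker count (evenly spaced, deterministic)
    if len(pos) > config.mosaic_sites:
        pick = np.linspace(0, len(pos) - 1, config.mosaic_sites).round().astype(int)
        pick = np.unique(pick)
        haps_all = haps_all[pick]
        pos = pos[pick]
    pop_index = {p.metadata.get("name", str(p.id)): p.id for p in mts.populations()}
    samp1 = mts.samples(population=pop_index[s1])
    samp2 = mts.samples(population=pop_index[s2])
    pool1 = haps_all[:, samp1[: n_pool]]
    ref1 = haps_all[:, samp1[n_pool:]]
    pool2 = haps_all[:, samp2[: n_pool]]
    ref2 = haps_all[:, samp2[n_pool:]]

    cm = pos / chrom_bp * morgans * 100.0
    morgan_pos = cm / 100.0
    n_hap_adm = 2 * n_target_dip
    adm = np.zeros((haps_all.shape[0], n_hap_adm), dtype=np.int8)
    block_lengths: list[float] = []
    anc1_len = 0.0
    pools = (pool1, pool2)
    for h in range(n_hap_adm):
        x = 0.0
        breaks = [0.0]
        while x < morgans:
            x += rng.exponential(1.0 / g)
            breaks.append(min(x, morgans))
        for k in range(len(breaks) - 1):
            lo, hi = breaks[k], breaks[k + 1]
            if hi > lo:
                block_lengths.append(hi - lo)
            anc = 0 if rng.random() < prop else 1
            if anc == 0:
                anc1_len += hi - lo
            pool = pools[anc]
            donor = int(rng.integers(pool.shape[1]))
            in_seg = (morgan_pos >= lo) & (morgan_pos < hi)
            adm[in_seg, h] = pool[in_seg, donor]
    total_len = morgans * n_hap_adm

    def diploidize(hmat: np.ndarray) -> np.ndarray:
        return (hmat[:, 0::2] + hmat[:, 1::2]).astype(np.int8)

    sample_names: list[str] = []
    pop_of: dict[str, str] = {}
    call_blocks: list[np.ndarray] = []
    for pop, hmat in ((target, adm), (s1, ref1), (s2, ref2)):
        dip = diploidize(hmat)
        for i in range(dip.shape[1]):
            name = f"{pop}_{i}"
            sample_names.append(name)
            pop_of[name] = pop
        call_blocks.append(dip)
    calls = np.concatenate(call_blocks, axis=1)
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * len(pos),
            "pos": pos,
            "ref": ["A"] * len(pos),
            "alt": ["C"] * len(pos),
            "qual": [100.0] * len(pos),
        }
    )
    gm = GenotypeMatrix(samples=sample_names, sites=sites, calls=calls)
    gmap = pd.DataFrame({"chrom": ["chr1"] * len(pos), "pos": pos, "cM": cm})
    return MosaicDataset(
        gm=gm,
        popmap=PopulationMap(pop_of),
        genetic_map=gmap,
        haplotypes={target: adm, s1: ref1, s2: ref2},
        block_lengths_morgans=np.array(block_lengths),
        ancestry_fraction=anc1_len / total_len,
        target=target,
    )


def emit_vcf(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    vcf_path,
    popmap_path,
    genetic_map: pd.DataFrame | None = None,
    genetic_map_path=None,
) -> None:
    """Write a dataset as VCF + popmap TSV (+ optional genetic map TSV)."""
    write_vcf(gm, vcf_path)
    write_popmap(popmap, popmap_path)
    if genetic_map is not None and genetic_map_path is not None:
        write_genetic_map(genetic_map, genetic_map_path)
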