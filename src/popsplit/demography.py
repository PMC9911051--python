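"""Two-population divergence-model fitting on joint folded spectra.

The model family is an isolation(-with-migration) scenario: an ancestral
population of size N_anc splits T time units ago (T in units of 2 N_anc
generations, the diffusion convention) into descendants of relative sizes
nu1 and nu2, with optional continuous scaled migration m12 (into
population 1 from population 2) and m21, both in units of 2 N_anc m per
generation.

The expected folded joint SFS under a model is computed by a Monte-Carlo
coalescent engine: branch-length frequency spectra averaged over a fixed
set of independent genealogies (common random numbers across optimizer
evaluations, so the likelihood surface is deterministic given the engine
seed).  Observed spectra are compared by Poisson composite likelihood
with the overall scaling theta profiled out in closed form, and theta
maps to real units through theta = 4 N_anc mu L.

Optimization is a seeded genetic algorithm in log-parameter space
followed by derivative-free simplex refinement; uncertainty comes from
10-kb block-bootstrap pseudo-replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .core import GenotypeMatrix, PopulationMap
from .popgen import JointSFS, default_joint_mask, fold_joint

logger = logging.getLogger(__name__)

FAMILIES = ("no_migration", "unidirectional", "bidirectional")

_N_PARAMS = {"no_migration": 3, "unidirectional": 4, "bidirectional": 5}

# vanishing migration rate used to align the engine's event structure
# across families: at this rate no migration event is ever realized, so the
# genealogy stream is identical to a richer family's at m -> 0
M_ALIGN = 1e-8


@dataclass
class SplitModel:
    """Divergence-model parameters in diffusion units."""

    family: str
    nu1: float
    nu2: float
    T: float
    m12: float = 0.0
    m21: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if min(self.nu1, self.nu2, self.T) <= 0:
            raise ValueError("nu1, nu2, T must be positive")
        if self.m12 < 0 or self.m21 < 0:
            raise ValueError("migration rates must be >= 0")
        if self.family == "no_migration" and (self.m12 or self.m21):
            raise ValueError("no_migration family requires m12 = m21 = 0")
        if self.family == "unidirectional" and self.m21:
            raise ValueError("unidirectional family fixes m21 = 0")

    def to_vector(self) -> np.ndarray:
        vec = [self.nu1, self.nu2, self.T]
        if self.family in ("unidirectional", "bidirectional"):
            vec.append(self.m12)
        if self.family == "bidirectional":
            vec.append(self.m21)
        return np.array(vec)

    @classmethod
    def from_vector(cls, family: str, vec: np.ndarray) -> "SplitModel":
        vec = np.asarray(vec, dtype=float)
        m12 = vec[3] if family in ("unidirectional", "bidirectional") else 0.0
        m21 = vec[4] if family == "bidirectional" else 0.0
        return cls(family=family, nu1=vec[0], nu2=vec[1], T=vec[2], m12=m12, m21=m21)


@dataclass
class EngineSettings:
    """Monte-Carlo expected-SFS engine configuration."""

    n_genealogies: int = 200
    N_ref: float = 1000.0
    seed: int = 987_001


def expected_joint_sfs(
    model: SplitModel, n1: int, n2: int, settings: EngineSettings | None = None
) -> JointSFS:
    """Expected folded joint SFS under the model, on the unit-theta scale.

    Entries scale linearly with theta: the expected observed count in a
    cell is ``theta * E[cell]`` with ``theta = 4 N_anc mu L``.  Computed
    as the mean branch-length frequency spectrum over independent
    Monte-Carlo genealogies divided by 4 N_ref, then folded.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must be >= 2")
    settings = settings or EngineSettings()
    # haploid-lineage engine: with ploidy=1 the pairwise coalescent time in a
    # population of size s is s generations, so s = N_ref plays the role of
    # one diffusion time unit (2 N_anc real generations); times and rates
    # below are expressed in that unit.
    n_ref = settings.N_ref
    dem = msprime.Demography()
    dem.add_population(name="ANC", initial_size=n_ref)
    dem.add_population(name="P1", initial_size=model.nu1 * n_ref)
    dem.add_population(name="P2", initial_size=model.nu2 * n_ref)
    dem.add_population_split(
        time=model.T * n_ref, derived=["P1", "P2"], ancestral="ANC"
    )
    # scaled m12 = 2 N_anc * (forward fraction of pop1 replaced from pop2).
    # Rates are floored at the vanishing alignment rate M_ALIGN so that every
    # family presents the same event structure to the simulator: common
    # random numbers then hold across nested families, not just within one.
    dem.set_migration_rate(source="P1", dest="P2", rate=max(model.m12, M_ALIGN) / n_ref)
    dem.set_migration_rate(source="P2", dest="P1", rate=max(model.m21, M_ALIGN) / n_ref)
    reps = msprime.sim_ancestry(
        samples={"P1": n1, "P2": n2},
        ploidy=1,
        demography=dem,
        sequence_length=1,
        num_replicates=settings.n_genealogies,
        random_seed=settings.seed,
    )
    afs = np.zeros((n1 + 1, n2 + 1))
    for ts in reps:
        s1 = ts.samples(population=1)
        s2 = ts.samples(population=2)
        afs += ts.allele_frequency_spectrum(
            [s1, s2], mode="branch", polarised=True, span_normalise=False
        )
    afs /= settings.n_genealogies
    # real branch lengths are (2 N_anc / N_ref) x engine branch lengths, so
    # expected counts are theta * AFS / (2 N_ref) with theta = 4 N_anc mu L
    expected = fold_joint(afs) / (2.0 * n_ref)
    return JointSFS(n1=n1, n2=n2, counts=expected, L=1.0)


def poisson_composite_loglik(
    observed: JointSFS, expected: JointSFS, eps: float = 1e-6
) -> tuple[float, float]:
    """Composite log-likelihood and the closed-form optimal theta.

    theta_hat = sum(obs) / sum(exp) over unmasked cells maximizes
    ``sum[obs * log(theta * exp) - theta * exp]`` (the Poisson likelihood
    up to the obs-dependent constant).  Expected cells that are zero where
    observed mass exists are floored at ``eps`` and logged; the default
    floor sits well below the resolution of the Monte-Carlo engine (one
    genealogy's worth of branch mass), so a floored cell reads as "rarer
    than the engine can measure" rather than impossible.
    """
    if observed.counts.shape != expected.counts.shape:
        raise ValueError("observed and expected grids differ in shape")
    mask = observed.mask & expected.mask
    obs = observed.counts[mask]
    exp = expected.counts[mask].copy()
    bad = (exp <= 0) & (obs > 0)
    if bad.any():
        logger.info("poisson_composite_loglik: %d zero expected cells floored", bad.sum())
        exp[bad] = eps
    total_obs = obs.sum()
    total_exp = exp.sum()
    if total_obs == 0:
        return 0.0, 0.0
    theta = total_obs / total_exp
    lam = theta * exp
    pos = obs > 0
    ll = float(np.sum(obs[pos] * np.log(lam[pos])) - lam.sum())
    return ll, float(theta)


@dataclass
class FitBounds:
    nu_min: float = 0.05
    nu_max: float = 20.0
    T_min: float = 1e-3
    T_max: float = 5.0
    m_min: float = 1e-4
    m_max: float = 10.0
    T_years_max: float | None = None  # enforced through the theta scaling

    def log_bounds(self, family: str) -> tuple[np.ndarray, np.ndarray]:
        lo = [self.nu_min, self.nu_min, self.T_min]
        hi = [self.nu_max, self.nu_max, self.T_max]
        n_extra = _N_PARAMS[family] - 3
        lo += [self.m_min] * n_extra
        hi += [self.m_max] * n_extra
        return np.log(np.array(lo)), np.log(np.array(hi))


@dataclass
class GASettings:
    """Genetic-algorithm hyperparameters (log-parameter space)."""

    population: int = 20
    generations: int = 25
    tournament: int = 3
    elite: int = 2
    crossover_rate: float = 0.7
    mutation_sd: float = 0.35
    mutation_decay: float = 0.97
    local_maxiter: int = 200


@dataclass
class FitResult:
    model: SplitModel
    theta_hat: float
    loglik: float
    converted: dict[str, float] | None = None
    sd: dict[str, float] | None = None
    n_evaluations: int = 0
    at_bound: list[str] = field(default_factory=list)
    converged: bool = True


def _t_years(theta: float, model: SplitModel, mu: float, L: float, gen_time: float) -> float:
    n_anc = theta / (4.0 * mu * L)
    return 2.0 * n_anc * model.T * gen_time


def fit_split_model(
    observed: JointSFS,
    family: str,
    seed: int,
    bounds: FitBounds | None = None,
    engine: EngineSettings | None = None,
    ga: GASettings | None = None,
    start: SplitModel | None = None,
    method: str = "ga+local",
    mu: float = 4e-9,
    generation_time: float = 1.0,
) -> FitResult:
    """Maximize the Poisson composite likelihood over one model family.

    A seeded GA (tournament selection, blend crossover and Gaussian
    mutation in log-parameter space, elitism) explores globally, followed
    by Nelder-Mead refinement; ``method="local"`` skips the GA and
    refines from ``start``.  A ``T_years_max`` bound is enforced as a
    penalty through the theta-implied unit conversion.  Deterministic for
    a fixed seed.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    bounds = bounds or FitBounds()
    engine = engine or EngineSettings()
    ga = ga or GASettings()
    lo, hi = bounds.log_bounds(family)
    ndim = len(lo)
    rng = np.random.default_rng(seed)
    n_evals = 0

    def objective(logp: np.ndarray) -> tuple[float, float]:
        nonlocal n_evals
        n_evals += 1
        p = np.exp(np.clip(logp, lo, hi))
        model = SplitModel.from_vector(family, p)
        exp = expected_joint_sfs(model, observed.n1, observed.n2, engine)
        ll, theta = poisson_composite_loglik(observed, exp)
        if bounds.T_years_max is not None and theta > 0:
            ty = _t_years(theta, model, mu, observed.L * 1.0, generation_time)
            if ty > bounds.T_years_max:
                ll -= 1e3 * (ty / bounds.T_years_max - 1.0) ** 2 + 10.0
        return ll, theta

    if method == "local":
        if start is None:
            raise ValueError('method="local" requires a start model')
        best_logp = np.log(start.to_vector())
    elif method == "ga+local":
        pop = rng.uniform(lo, hi, size=(ga.population, ndim))
        if start is not None:
            pop[0] = np.clip(np.log(start.to_vector()), lo, hi)
        fitness = np.array([objective(ind)[0] for ind in pop])
        sd = ga.mutation_sd
        for _ in range(ga.generations):
            order = np.argsort(fitness)[::-1]
            new_pop = [pop[i].copy() for i in order[: ga.elite]]
            while len(new_pop) < ga.population:
                picks = rng.integers(0, ga.population, size=ga.tournament)
                pa = pop[picks[np.argmax(fitness[picks])]]
                picks = rng.integers(0, ga.population, size=ga.tournament)
                pb = pop[picks[np.argmax(fitness[picks])]]
                if rng.random() < ga.crossover_rate:
                    alpha = rng.uniform(-0.25, 1.25, size=ndim)
                    child = alpha * pa + (1 - alpha) * pb
                else:
                    child = pa.copy()
                child += rng.normal(0.0, sd, size=ndim)
                new_pop.append(np.clip(child, lo, hi))
            pop = np.array(new_pop)
            fitness = np.array([objective(ind)[0] for ind in pop])
            sd *= ga.mutation_decay
        best_logp = pop[int(np.argmax(fitness))]
    else:
        raise ValueError(f"unknown method {method!r}")

    res = minimize(
        lambda lp: -objective(lp)[0],
        best_logp,
        method="Nelder-Mead",
        options={"maxiter": ga.local_maxiter, "xatol": 1e-4, "fatol": 1e-4},
    )
    final_logp = np.clip(res.x, lo, hi)
    ll, theta = objective(final_logp)
    n_evals_final = n_evals
    model = SplitModel.from_vector(family, np.exp(final_logp))
    names = ["nu1", "nu2", "T", "m12", "m21"][:ndim]
    at_bound = [
        nm
        for nm, v, l, h in zip(names, final_logp, lo, hi)
        if v <= l + 1e-9 or v >= h - 1e-9
    ]
    if at_bound:
        logger.warning("fit_split_model: optimum at bound for %s", at_bound)
    return FitResult(
        model=model,
        theta_hat=theta,
        loglik=ll,
        n_evaluations=n_evals_final,
        at_bound=at_bound,
        converged=bool(res.success or res.status == 1),
    )


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(fit_null: FitResult, fit_alt: FitResult) -> LRTResult:
    """Chi-squared LRT between nested model families.

    statistic = 2 (loglik_alt - loglik_null), clamped at zero; degrees of
    freedom are the added migration parameters.

    The statistic is only meaningful when both fits used the *same*
    :class:`EngineSettings` (count and seed): the engine's event
    structure is identical across families (migration entries are always
    present, floored at a vanishing rate), so the two composite
    log-likelihoods live on one common Monte-Carlo surface and their
    shared noise cancels in the difference.  Warm-starting the richer
    family from the null optimum makes the comparison a true nested
    optimization on that surface.
    """
    df = _N_PARAMS[fit_alt.model.family] - _N_PARAMS[fit_null.model.family]
    if df <= 0:
        raise ValueError(
            f"{fit_null.model.family!r} is not nested in {fit_alt.model.family!r}"
        )
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    return LRTResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def convert_units(
    fit: FitResult,
    mu: float = 4e-9,
    L: float | None = None,
    generation_time: float = 1.0,
) -> dict[str, float]:
    """Convert scaled parameters to individuals, years and per-generation
    migration fractions via theta = 4 N_anc mu L."""
    if min(mu, generation_time) <= 0 or (L is not None and L <= 0):
        raise ValueError("mu, L, generation_time must be positive")
    if fit.theta_hat <= 0:
        raise ValueError("theta_hat <= 0: conversion undefined")
    L = 1.0 if L is None else L
    n_anc = fit.theta_hat / (4.0 * mu * L)
    m = fit.model
    conv = {
        "N_anc": n_anc,
        "N1": m.nu1 * n_anc,
        "N2": m.nu2 * n_anc,
        "T_years": 2.0 * n_anc * m.T * generation_time,
        "m12_per_gen": m.m12 / (2.0 * n_anc),
        "m21_per_gen": m.m21 / (2.0 * n_anc),
    }
    fit.converted = conv
    return conv


# ---------------------------------------------------------------------------
# block bootstrap


def site_blocks(gm: GenotypeMatrix, block_bp: int = 10_000) -> list[np.ndarray]:
    """Indices of sites grouped into non-overlapping genomic blocks."""
    if block_bp <= 0:
        raise ValueError("block_bp must be positive")
    keys = list(
        zip(gm.sites["chrom"], (gm.sites["pos"].to_numpy() - 1) // block_bp)
    )
    blocks: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        blocks.setdefault(k, []).append(i)
    return [np.array(v) for _, v in sorted(blocks.items(), key=lambda kv: kv[0])]


def block_bootstrap(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    n1: int | None = None,
    n2: int | None = None,
    block_bp: int = 10_000,
    n_reps: int = 100,
    seed: int = 0,
    block_choices: np.ndarray | None = None,
) -> list[JointSFS]:
    """Joint-SFS pseudo-replicates by resampling genomic blocks.

    Each replicate draws the original number of blocks with replacement
    and sums their per-block folded joint spectra (folding is linear, so
    per-block grids add exactly).  ``block_choices`` overrides the random
    draw (one row of block indices per replicate), e.g. the identity for
    a consistency check.
    """
    from .popgen import joint_folded_sfs

    blocks = site_blocks(gm, block_bp)
    n_blocks = len(blocks)
    if n_blocks < 10:
        logger.warning("block_bootstrap: only %d blocks; SDs unreliable", n_blocks)
    grids = []
    ref = None
    for idx in blocks:
        sub = gm.take_sites(idx)
        sfs = joint_folded_sfs(sub, popmap, pop_a, pop_b, n1, n2)
        grids.append(sfs)
        ref = sfs
    assert ref is not None
    stack = np.array([g.counts for g in grids])
    ls = np.array([g.L for g in grids])
    rng = np.random.default_rng(seed)
    if block_choices is None:
        block_choices = rng.integers(0, n_blocks, size=(n_reps, n_blocks))
    out = []
    for row in block_choices:
        counts = stack[row].sum(axis=0)
        out.append(JointSFS(n1=ref.n1, n2=ref.n2, counts=counts, L=float(ls[row].sum())))
    return out


def bootstrap_parameter_sds(
    fit: FitResult,
    replicates: list[JointSFS],
    seed: int,
    engine: EngineSettings | None = None,
    ga: GASettings | None = None,
    mu: float = 4e-9,
    generation_time: float = 1.0,
) -> dict[str, float]:
    """Per-parameter SDs by refitting each pseudo-replicate from the MLE."""
    ga = ga or GASettings(local_maxiter=80)
    rows = []
    for r, rep in enumerate(replicates):
        refit = fit_split_model(
            rep,
            fit.model.family,
            seed=seed + r,
            engine=engine,
            ga=ga,
            start=fit.model,
            method="local",
            mu=mu,
            generation_time=generation_time,
        )
        vec = refit.model.to_vector()
        rows.append(np.append(vec, refit.theta_hat))
    arr = np.array(rows)
    names = ["nu1", "nu2", "T", "m12", "m21"][: arr.shape[1] - 1] + ["theta"]
    sds = {nm: float(np.std(arr[:, i], ddof=1)) for i, nm in enumerate(names)}
    fit.sd = sds
    return sds
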