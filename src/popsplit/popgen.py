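"""Summary statistics of variation.

Site frequency spectra (folded, one- and two-dimensional, with
hypergeometric projection to a common sample size), nucleotide diversity,
Watterson's theta, Tajima's D, and the Weir & Cockerham (1984) weighted
F_st estimator from variance components.

All estimators work on called genotypes; the per-site sample size adapts
to missingness where the estimator allows it (pi), while theta_W and
Tajima's D use a single nominal haploid size n (the population's 2x
diploid count by default), with constants following Tajima (1989).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# spectra


@dataclass
class FoldedSFS:
    """Folded site frequency spectrum.

    ``counts[i]`` is the (possibly fractional, after projection) number of
    sites with minor-allele count ``i`` out of ``n`` chromosomes; entry 0
    holds the monomorphic-site mass when ``L`` accounting includes it.
    """

    n: int
    counts: np.ndarray
    L: float

    @property
    def S(self) -> float:
        """Segregating-site mass (classes 1..floor(n/2))."""
        return float(self.counts[1:].sum())


@dataclass
class JointSFS:
    """Folded two-dimensional SFS on an ``(n1+1) x (n2+1)`` grid.

    Cells (i, j) and (n1-i, n2-j) are merged onto the orientation with the
    smaller total count i+j; ties keep the lexicographically smaller index
    pair.  ``mask`` marks cells excluded from likelihoods (the monomorphic
    corners by default).
    """

    n1: int
    n2: int
    counts: np.ndarray
    L: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("joint SFS grid shape mismatch")
        if self.mask is None:
            self.mask = default_joint_mask(self.n1, self.n2)


def default_joint_mask(n1: int, n2: int) -> np.ndarray:
    """True where cells enter the likelihood: everything except the
    monomorphic corners (0,0) and (n1,n2)."""
    mask = np.ones((n1 + 1, n2 + 1), dtype=bool)
    mask[0, 0] = False
    mask[n1, n2] = False
    return mask


def fold_joint(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded joint spectrum by merging (i,j) with (n1-i, n2-j).

    The merged mass lands on the orientation with the smaller total allele
    count; exact ties keep the lexicographically smaller index pair.  The
    operation is an involution-consistent merge: each unordered pair is
    counted exactly once.
    """
    n1 = unfolded.shape[0] - 1
    n2 = unfolded.shape[1] - 1
    folded = np.zeros_like(unfolded, dtype=float)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            pi, pj = n1 - i, n2 - j
            tot, ptot = i + j, pi + pj
            if tot < ptot:
                target = (i, j)
            elif tot > ptot:
                target = (pi, pj)
            else:
                target = min((i, j), (pi, pj))
            if (i, j) == target:
                folded[i, j] += unfolded[i, j]
                if (pi, pj) != (i, j):
                    folded[i, j] += unfolded[pi, pj]
    return folded


def _projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """Row k: hypergeometric distribution of the projected allele count
    when k of ``n_from`` chromosomes carry the allele and ``n_to`` are
    drawn without replacement."""
    k = np.arange(n_from + 1)[:, None]
    j = np.arange(n_to + 1)[None, :]
    return hypergeom.pmf(j, n_from, k, n_to)


def _pop_indices(gm: GenotypeMatrix, popmap: PopulationMap, population: str) -> np.ndarray:
    popmap.validate_against(gm)
    return gm.sample_indices(popmap.samples_of(population))


def folded_sfs(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    projection_n: int | None = None,
    include_monomorphic: bool = True,
) -> FoldedSFS:
    """Folded SFS of one population, hypergeometrically projected to
    ``projection_n`` chromosomes (default: the full 2 x diploid count).

    Sites with fewer callable chromosomes than the projection are dropped;
    the contribution of a site with ``m >= projection_n`` callable
    chromosomes and alt count c is the hypergeometric distribution of the
    alt count in a draw of ``projection_n``, folded to minor-allele counts.
    Deterministic when all sites are fully called.
    """
    idx = _pop_indices(gm, popmap, population)
    n_full = 2 * len(idx)
    n = n_full if projection_n is None else int(projection_n)
    if n < 2 or n > n_full:
        raise ValueError(f"projection_n must be in [2, {n_full}]")
    alt, called = gm.alt_counts(idx)
    usable = called >= n
    unfolded = np.zeros(n + 1)
    for m in np.unique(called[usable]):
        proj = _projection_matrix(int(m), n)
        sel = usable & (called == m)
        counts = np.bincount(alt[sel], minlength=int(m) + 1)
        unfolded += counts @ proj
    half = n // 2
    counts = np.zeros(half + 1)
    for k in range(n + 1):
        counts[min(k, n - k)] += unfolded[k]
    L = float(usable.sum())
    if not include_monomorphic:
        counts[0] = 0.0
    return FoldedSFS(n=n, counts=counts, L=L)


def joint_folded_sfs(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    n1: int | None = None,
    n2: int | None = None,
) -> JointSFS:
    """Folded joint SFS of two disjoint populations with projection.

    Raises ``ValueError`` if the two populations share samples.
    """
    idx_a = _pop_indices(gm, popmap, pop_a)
    idx_b = _pop_indices(gm, popmap, pop_b)
    if set(idx_a) & set(idx_b):
        raise ValueError(f"populations {pop_a!r} and {pop_b!r} share samples")
    n1 = 2 * len(idx_a) if n1 is None else int(n1)
    n2 = 2 * len(idx_b) if n2 is None else int(n2)
    alt_a, called_a = gm.alt_counts(idx_a)
    alt_b, called_b = gm.alt_counts(idx_b)
    usable = (called_a >= n1) & (called_b >= n2)
    unfolded = np.zeros((n1 + 1, n2 + 1))
    # per unique pair of callable counts, the site contributions are rows of
    # fixed projection matrices, so the accumulated grid is one matmul
    pair_keys = called_a * (2 * gm.n_samples + 1) + called_b
    for key in np.unique(pair_keys[usable]):
        sel = usable & (pair_keys == key)
        m_a = int(called_a[np.flatnonzero(sel)[0]])
        m_b = int(called_b[np.flatnonzero(sel)[0]])
        rows_a = _projection_matrix(m_a, n1)[alt_a[sel]]
        rows_b = _projection_matrix(m_b, n2)[alt_b[sel]]
        unfolded += rows_a.T @ rows_b
    folded = fold_joint(unfolded)
    return JointSFS(n1=n1, n2=n2, counts=folded, L=float(usable.sum()))


def equilibrium_folded_expectation(n: int) -> np.ndarray:
    """Relative expected folded spectrum under the standard neutral model.

    Unfolded E[xi_k] is proportional to 1/k; folding gives
    ``1/i + 1/(n-i)`` for i < n/2 and ``1/i`` at i = n/2 (even n).
    Returned over classes 1..floor(n/2), normalized to sum 1.
    """
    half = n // 2
    e = np.zeros(half)
    for i in range(1, half + 1):
        e[i - 1] = 1.0 / i + (1.0 / (n - i) if i != n - i else 0.0)
    return e / e.sum()


def write_folded_sfs(sfs: FoldedSFS, path) -> None:
    """dadi-style flat text: header with n and L, then the count vector."""
    with open(path, "w") as fh:
        fh.write(f"# folded SFS n={sfs.n} L={sfs.L:g}\n")
        fh.write(" ".join(f"{c:.10g}" for c in sfs.counts) + "\n")


def write_joint_sfs(sfs: JointSFS, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# folded joint SFS n1={sfs.n1} n2={sfs.n2} L={sfs.L:g}\n")
        fh.write(" ".join(f"{c:.10g}" for c in sfs.counts.ravel()) + "\n")


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityStats:
    """Per-site diversity summaries for one population sample."""

    pi: float
    theta_w: float
    tajima_d: float
    S: int
    n: int
    L: int
    population: str = ""


def harmonic(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def _tajima_constants(n: int) -> tuple[float, float, float]:
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, e1, e2


def diversity_stats(
    gm: GenotypeMatrix, popmap: PopulationMap, population: str
) -> DiversityStats:
    """pi, Watterson's theta_W and Tajima's D for one population.

    Per site, the pi contribution is ``2 c (m - c) / (m (m - 1))`` with m
    the callable chromosomes there and c the alt count.  theta_W is
    ``S / (a_{n-1} L)`` with n the nominal haploid size; Tajima's D uses
    the full variance normalization of the standard neutrality test and is
    0 whenever its numerator is 0.
    """
    idx = _pop_indices(gm, popmap, population)
    n = 2 * len(idx)
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    alt, called = gm.alt_counts(idx)
    usable = called >= 2
    L = int(usable.sum())
    if L == 0:
        raise ValueError("no callable sites (L = 0)")
    c = alt[usable].astype(float)
    m = called[usable].astype(float)
    pi_sum = float(np.sum(2.0 * c * (m - c) / (m * (m - 1.0))))
    seg = (c > 0) & (c < m)
    S = int(seg.sum())
    a1, e1, e2 = _tajima_constants(n)
    theta_w = S / (a1 * L)
    num = pi_sum - S / a1
    if num == 0.0 or S == 0:
        d = 0.0
    else:
        d = num / np.sqrt(e1 * S + e2 * S * (S - 1.0))
    return DiversityStats(
        pi=pi_sum / L, theta_w=theta_w, tajima_d=float(d), S=S, n=n, L=L,
        population=population,
    )


def diversity_from_sfs(sfs: FoldedSFS) -> tuple[float, float]:
    """(pi, theta_W) per site recomputed from a folded spectrum.

    Independent of the genotype-based path: pi weights each folded class i
    by ``2 i (n - i) / (n (n - 1))``; agrees with :func:`diversity_stats`
    on fully called data.
    """
    n = sfs.n
    i = np.arange(len(sfs.counts))
    pi_sum = float(np.sum(sfs.counts * 2.0 * i * (n - i) / (n * (n - 1.0))))
    theta = sfs.S / (harmonic(n - 1) * sfs.L)
    return pi_sum / sfs.L, theta


# ---------------------------------------------------------------------------
# F_st


@dataclass
class FstResult:
    """Weir-Cockerham weighted F_st with its summed variance components."""

    fst: float
    a: float
    b: float
    c: float


def weir_cockerham_fst(
    gm: GenotypeMatrix, popmap: PopulationMap, pop_a: str, pop_b: str
) -> FstResult:
    """Weighted two-population F_st per Weir & Cockerham (1984).

    Per-site variance components a (among populations), b (among
    individuals within populations) and c (within individuals) are summed
    over sites and the weighted ratio ``sum(a) / sum(a + b + c)`` returned.
    Raises ``ValueError`` when no site is polymorphic (denominator 0).
    """
    idx = [_pop_indices(gm, popmap, p) for p in (pop_a, pop_b)]
    for p, ix in zip((pop_a, pop_b), idx):
        if len(ix) < 2:
            raise ValueError(f"population {p!r} needs >= 2 diploid samples")
    r = 2
    sum_a = sum_b = sum_c = 0.0
    calls = [gm.calls[:, ix] for ix in idx]
    for s in range(gm.n_sites):
        n_i, p_i, h_i = [], [], []
        for cal in calls:
            g = cal[s]
            g = g[g >= 0]
            if len(g) < 1:
                break
            n_i.append(len(g))
            p_i.append(g.sum() / (2.0 * len(g)))
            h_i.append(np.mean(g == 1))
        else:
            n_i = np.array(n_i, dtype=float)
            p_i = np.array(p_i)
            h_i = np.array(h_i)
            n_tot = n_i.sum()
            nbar = n_tot / r
            if n_tot <= r or nbar <= 1:
                continue
            nc = (n_tot - np.sum(n_i**2) / n_tot) / (r - 1)
            pbar = np.sum(n_i * p_i) / n_tot
            s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
            hbar = np.sum(n_i * h_i) / n_tot
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            cc = hbar / 2.0
            sum_a += a
            sum_b += b
            sum_c += cc
    denom = sum_a + sum_b + sum_c
    if denom == 0.0:
        raise ValueError("F_st undefined: no polymorphic sites")
    return FstResult(fst=sum_a / denom, a=sum_a, b=sum_b, c=sum_c)


# ---------------------------------------------------------------------------
# reporting


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (matching printed-table conventions)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def summarize_diversity(
    stats: list[DiversityStats],
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-population diversity table (theta_W %, pi %, Tajima's D) with
    optional group arithmetic means appended; percentages rounded half away
    from zero to 3 decimals, group means to 2."""
    rows = [
        {
            "population": st.population,
            "theta_w_pct": round_half_away(100.0 * st.theta_w, 3),
            "pi_pct": round_half_away(100.0 * st.pi, 3),
            "tajima_d": round_half_away(st.tajima_d, 3),
        }
        for st in stats
    ]
    df = pd.DataFrame(rows)
    if groups:
        by_pop = {st.population: st for st in stats}
        for name, members in groups.items():
            sub = [by_pop[m] for m in members]
            df = pd.concat(
                [
                    df,
                    pd.DataFrame(
                        [
                            {
                                "population": f"mean({name})",
                                "theta_w_pct": round_half_away(
                                    100.0 * float(np.mean([s.theta_w for s in sub])), 2
                                ),
                                "pi_pct": round_half_away(
                                    100.0 * float(np.mean([s.pi for s in sub])), 2
                                ),
                                "tajima_d": round_half_away(
                                    float(np.mean([s.tajima_d for s in sub])), 2
                                ),
                            }
                        ]
                    ),
                ],
                ignore_index=True,
            )
    return df
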