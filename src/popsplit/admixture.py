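"""Admixture detection and dating.

Two complementary signals:

* the three-population f3 statistic E[(p_T - p_B)(p_T - p_C)] with the
  finite-sample correction for the target's heterozygosity — significantly
  negative values indicate the target is admixed between sources related
  to B and C; uncertainty by leave-one-block-out jackknife over
  consecutive SNP blocks;
* allele-frequency-difference-weighted LD in the target, which decays
  exponentially with genetic distance at a rate equal to the number of
  generations since admixture, fitted as amp * exp(-decay * d) + affine.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)


def enumerate_triples(populations: list[str]) -> list[tuple[str, str, str]]:
    """All unordered 3-subsets of the given population labels."""
    if len(set(populations)) != len(populations):
        raise ValueError("duplicate population labels")
    if len(populations) < 3:
        raise ValueError("need at least 3 populations")
    return list(itertools.combinations(populations, 3))


@dataclass
class F3Result:
    target: str
    ref_b: str
    ref_c: str
    f3: float
    se: float
    z: float
    n_sites: int
    n_blocks: int


def _freqs(gm: GenotypeMatrix, popmap: PopulationMap, pop: str):
    idx = gm.sample_indices(popmap.samples_of(pop))
    alt, called = gm.alt_counts(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    return p, called


def f3_statistic(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    target: str,
    ref_b: str,
    ref_c: str,
    block_size_snps: int = 500,
) -> F3Result:
    """f3(target; B, C) with block-jackknife standard error.

    Per-site contribution is ``(pT - pB)(pT - pC) - pT(1 - pT)/(nT - 1)``
    (nT = called target chromosomes), which removes the upward bias from
    sampling noise in the target frequency.  The statistic is the mean
    over informative sites; the SE comes from a delete-one jackknife over
    consecutive blocks of ``block_size_snps`` SNPs.  Symmetric in B and C.
    """
    if len({target, ref_b, ref_c}) != 3:
        raise ValueError("target and references must be three distinct populations")
    p_t, n_t = _freqs(gm, popmap, target)
    p_b, n_b = _freqs(gm, popmap, ref_b)
    p_c, n_c = _freqs(gm, popmap, ref_c)
    ok = (n_t >= 4) & (n_b >= 2) & (n_c >= 2)
    contrib = (
        (p_t - p_b) * (p_t - p_c) - p_t * (1.0 - p_t) / (n_t - 1.0)
    )[ok]
    n_sites = int(ok.sum())
    if n_sites == 0:
        raise ValueError("no informative sites for f3")
    f3 = float(np.mean(contrib))
    n_blocks = max(1, n_sites // block_size_snps)
    if n_blocks < 2:
        logger.warning("f3: fewer than 2 blocks; SE unavailable")
        return F3Result(target, ref_b, ref_c, f3, np.nan, np.nan, n_sites, n_blocks)
    blocks = np.array_split(contrib, n_blocks)
    total = contrib.sum()
    loo = np.array([(total - b.sum()) / (n_sites - len(b)) for b in blocks])
    jk_mean = loo.mean()
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - jk_mean) ** 2)))
    z = f3 / se if se > 0 else np.nan
    return F3Result(target, ref_b, ref_c, f3, se, float(z), n_sites, n_blocks)


def f3_scan(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    populations: list[str] | None = None,
    block_size_snps: int = 500,
) -> pd.DataFrame:
    """f3 for every (target; B, C) orientation of every 3-subset."""
    pops = populations or popmap.populations
    rows = []
    for trip in enumerate_triples(pops):
        for t_idx in range(3):
            target = trip[t_idx]
            refs = [p for p in trip if p != target]
            res = f3_statistic(gm, popmap, target, refs[0], refs[1], block_size_snps)
            rows.append(
                {
                    "target": res.target,
                    "ref_b": res.ref_b,
                    "ref_c": res.ref_c,
                    "f3": res.f3,
                    "se": res.se,
                    "z": res.z,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# weighted LD


@dataclass
class WeightedLDCurve:
    """Binned allele-frequency-difference-weighted LD of a target population."""

    mode: str  # "one-reference" | "two-reference"
    bins: np.ndarray  # bin midpoints, cM
    values: np.ndarray
    pair_counts: np.ndarray
    # per-site-block partial sums for jackknife: (n_bins, n_blocks)
    block_value_sums: np.ndarray = field(repr=False, default=None)  # type: ignore
    block_pair_counts: np.ndarray = field(repr=False, default=None)  # type: ignore
    value_sums: np.ndarray = field(repr=False, default=None)  # type: ignore


def weighted_ld_curve(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    target: str,
    ref1: str,
    ref2: str | None = None,
    genetic_map: pd.DataFrame | None = None,
    bin_width_cm: float = 0.05,
    min_cm: float = 0.5,
    max_cm: float = 30.0,
    haplotypes: np.ndarray | None = None,
    n_jackknife_blocks: int = 20,
) -> WeightedLDCurve:
    """Weighted LD of the target binned by genetic distance.

    Per SNP pair (x, y) the target's two-locus covariance (haplotype
    covariance when phased ``haplotypes`` are given, else half the
    genotype covariance) is weighted by ``w_x * w_y`` where the weights
    are reference allele-frequency differences: two-reference mode uses
    ``p_ref1 - p_ref2``; one-reference mode (``ref2`` absent) uses
    ``p_target - p_ref1``.  Pairs on different chromosomes are skipped.
    """
    if genetic_map is None:
        raise ValueError("genetic positions are required for weighted LD")
    cm = np.asarray(genetic_map["cM"], dtype=float)
    chroms = np.asarray(genetic_map["chrom"])
    if len(cm) != gm.n_sites:
        raise ValueError("genetic map does not cover all sites")
    p1, _ = _freqs(gm, popmap, ref1)
    if ref2 is not None:
        mode = "two-reference"
        p2, _ = _freqs(gm, popmap, ref2)
        w = p1 - p2
    else:
        mode = "one-reference"
        pt, _ = _freqs(gm, popmap, target)
        w = pt - p1
    w = np.nan_to_num(w)
    if haplotypes is not None:
        x = haplotypes.astype(float)
        scale = 1.0
    else:
        idx = gm.sample_indices(popmap.samples_of(target))
        x = gm.calls[:, idx].astype(float)
        x[x == MISSING] = np.nan
        scale = 0.5
    if x.shape[1] < 2:
        raise ValueError("target needs >= 2 chromosomes/samples")
    mu = np.nanmean(x, axis=1, keepdims=True)
    xc = np.nan_to_num(x - mu)
    n_eff = np.maximum((~np.isnan(x)).sum(axis=1), 2)
    cov = (xc @ xc.T) / (n_eff[:, None] - 1) * scale
    weighted = cov * np.outer(w, w)

    edges = np.arange(min_cm, max_cm + bin_width_cm, bin_width_cm)
    n_bins = len(edges) - 1
    mids = 0.5 * (edges[:-1] + edges[1:])
    s = gm.n_sites
    block_of = np.minimum(
        (np.arange(s) * n_jackknife_blocks) // s, n_jackknife_blocks - 1
    )
    iu, ju = np.triu_indices(s, k=1)
    same = chroms[iu] == chroms[ju]
    d = np.abs(cm[iu] - cm[ju])
    sel = same & (d >= min_cm) & (d < max_cm)
    iu, ju, d = iu[sel], ju[sel], d[sel]
    vals = weighted[iu, ju]
    which = np.minimum(((d - min_cm) / bin_width_cm).astype(int), n_bins - 1)

    tot_v = np.bincount(which, weights=vals, minlength=n_bins)
    tot_c = np.bincount(which, minlength=n_bins).astype(float)
    bv = np.zeros((n_bins, n_jackknife_blocks))
    bc = np.zeros((n_bins, n_jackknife_blocks))
    bi, bj = block_of[iu], block_of[ju]
    np.add.at(bv, (which, bi), vals)
    np.add.at(bc, (which, bi), 1.0)
    other = bi != bj
    np.add.at(bv, (which[other], bj[other]), vals[other])
    np.add.at(bc, (which[other], bj[other]), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(tot_c > 0, tot_v / np.maximum(tot_c, 1), np.nan)
    n_empty = int((tot_c == 0).sum())
    if n_empty:
        logger.info("weighted_ld_curve: %d empty bins excluded", n_empty)
    return WeightedLDCurve(
        mode=mode,
        bins=mids,
        values=values,
        pair_counts=tot_c,
        block_value_sums=bv,
        block_pair_counts=bc,
        value_sums=tot_v,
    )


@dataclass
class DecayFit:
    """Exponential-plus-affine fit of a weighted-LD curve.

    ``decay`` is in inverse Morgans and is read as generations since
    admixture; ``date_years = decay * generation_time``.
    """

    amp_exp: float
    decay: float
    affine: float
    se_decay: float
    se_amp: float
    z: float
    date_years: float
    se_date_years: float
    status: str  # "success" | "failure"
    generation_time: float = 1.0
    residuals: np.ndarray | None = None


def _fit_exp(d_morgan: np.ndarray, y: np.ndarray) -> tuple[float, float, float] | None:
    """amp, decay, affine for y = amp*exp(-decay*d) + affine; None on failure."""
    best = None
    for decay0 in np.geomspace(1.0, 2000.0, 25):
        basis = np.exp(-decay0 * d_morgan)
        a_mat = np.column_stack([basis, np.ones_like(basis)])
        coef, res, *_ = np.linalg.lstsq(a_mat, y, rcond=None)
        sse = float(np.sum((a_mat @ coef - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, coef[0], decay0, coef[1])
    assert best is not None
    p0 = [best[1], best[2], best[3]]
    try:
        popt, _ = curve_fit(
            lambda d, a, k, c: a * np.exp(-k * d) + c,
            d_morgan,
            y,
            p0=p0,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 1e5, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError):
        return None
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_decay(
    curve: WeightedLDCurve,
    d0_cm: float = 0.5,
    generation_time: float = 1.0,
    min_bins: int = 4,
    z_threshold: float = 2.0,
) -> DecayFit:
    """Least-squares exponential decay fit with jackknife uncertainty.

    Requires at least ``min_bins`` informative bins at distances beyond
    ``d0_cm``.  Status is "failure" when the optimizer does not converge
    or the amplitude is not distinguishable from zero (|z| below
    ``z_threshold``), mirroring how a flat curve carries no admixture
    date.
    """
    use = (curve.pair_counts > 0) & (curve.bins >= d0_cm) & np.isfinite(curve.values)
    if use.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} informative bins beyond d0")
    d = curve.bins[use] / 100.0  # Morgans
    y = curve.values[use]
    fit = _fit_exp(d, y)
    if fit is None:
        return DecayFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            status="failure", generation_time=generation_time,
        )
    amp, decay, affine = fit
    resid = y - (amp * np.exp(-decay * d) + affine)

    amps, decays = [], []
    if curve.block_value_sums is not None:
        n_blocks = curve.block_value_sums.shape[1]
        for b in range(n_blocks):
            v = curve.value_sums - curve.block_value_sums[:, b]
            c = curve.pair_counts - curve.block_pair_counts[:, b]
            ok = use & (c > 0)
            if ok.sum() < min_bins:
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                yb = (v / np.maximum(c, 1))[ok]
            fb = _fit_exp(curve.bins[ok] / 100.0, yb)
            if fb is not None:
                amps.append(fb[0])
                decays.append(fb[1])
    if len(decays) >= 2:
        k = len(decays)
        se_decay = float(np.sqrt((k - 1) / k * np.sum((np.array(decays) - np.mean(decays)) ** 2)))
        se_amp = float(np.sqrt((k - 1) / k * np.sum((np.array(amps) - np.mean(amps)) ** 2)))
    else:
        se_decay = se_amp = np.nan
    z = amp / se_amp if se_amp and np.isfinite(se_amp) and se_amp > 0 else 0.0
    status = "success" if np.isfinite(z) and abs(z) >= z_threshold else "failure"
    return DecayFit(
        amp_exp=amp,
        decay=decay,
        affine=affine,
        se_decay=se_decay,
        se_amp=se_amp,
        z=float(z),
        date_years=decay * generation_time,
        se_date_years=se_decay * generation_time,
        status=status,
        generation_time=generation_time,
        residuals=resid,
    )
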