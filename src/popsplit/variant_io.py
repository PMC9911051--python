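"""VCF reading/writing and the site-filtering cascade.

The cascade mirrors common practice for exome SNP panels: drop sites with
more than a missingness threshold or QUAL below a cutoff, remove
Hardy-Weinberg outliers with a per-population exact test, and greedily
prune linked sites by windowed genotype r-squared.

Coordinate conventions: VCF positions are 1-based inclusive throughout;
optional BED site masks are half-open 0-based and converted at the boundary.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (count logged); missing
    genotypes are preserved as missing.  Raises ``OSError`` for unreadable
    files and ``ValueError`` for a VCF without samples.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.REF not in _BASES or rec.ALT[0] not in _BASES:
            n_dropped += 1
            continue
        # gts012=True: gt_types is 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        quals.append(np.nan if rec.QUAL is None else float(rec.QUAL))
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "qual": quals}
    )
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT fields only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, sub in gm.sites.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        quals = gm.sites["qual"].to_numpy()
        for i in range(gm.n_sites):
            row = gm.sites.iloc[i]
            qual = "." if np.isnan(quals[i]) else f"{quals[i]:g}"
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.calls[i])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\tPASS\t.\tGT\t{gts}\n"
            )


def filter_sites(
    gm: GenotypeMatrix, max_missing_frac: float = 0.5, min_qual: float = 30.0
) -> GenotypeMatrix:
    """Remove sites with missing fraction above ``max_missing_frac`` or
    QUAL strictly below ``min_qual``.

    Both thresholds are strict in the direction of removal: a site is
    dropped iff ``missing_frac > max_missing_frac`` or ``qual < min_qual``.
    Sites with absent QUAL pass the quality test.  Order is preserved and
    the filter is idempotent.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    miss = gm.missing_fraction()
    qual = gm.sites["qual"].to_numpy(dtype=float)
    qual_ok = np.isnan(qual) | (qual >= min_qual)
    keep = (miss <= max_missing_frac) & qual_ok
    logger.info("filter_sites: %d -> %d sites", gm.n_sites, int(keep.sum()))
    return gm.take_sites(keep)


@lru_cache(maxsize=200_000)
def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value for one population.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities of configurations no more probable than the
    observed one (the standard exact test of HWE for biallelic genotype
    counts).  Monomorphic samples return 1.0.
    """
    n = n_het + n_hom1 + n_hom2
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    if n == 0 or n_rare == 0:
        return 1.0
    # P(n_het | n, n_rare) via the stable ratio recurrence, anchored at the
    # mid value; normalized at the end.
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het >= 2:
        # ratio P(het-2)/P(het)
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        ratio = het * (het - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        probs[het - 2] = probs[het] * ratio
        het -= 2
    het = mid
    while het + 2 <= n_rare:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        ratio = 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        probs[het + 2] = probs[het] * ratio
        het += 2
    total = sum(probs.values())
    p_obs = probs.get(n_het, 0.0) / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_filter(
    gm: GenotypeMatrix, popmap: PopulationMap, alpha: float = 1e-6
) -> GenotypeMatrix:
    """Remove sites failing the within-population exact HWE test.

    A site is dropped when its exact-test p-value is below ``alpha`` in
    *any* population (conservative).  Populations with fewer than two
    genotyped samples at a site are skipped for that site.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    popmap.validate_against(gm)
    keep = np.ones(gm.n_sites, dtype=bool)
    n_skipped = 0
    for pop in popmap.populations:
        idx = gm.sample_indices(popmap.samples_of(pop))
        calls = gm.calls[:, idx]
        n_het = (calls == 1).sum(axis=1)
        n_hom_ref = (calls == 0).sum(axis=1)
        n_hom_alt = (calls == 2).sum(axis=1)
        genotyped = n_het + n_hom_ref + n_hom_alt
        for i in range(gm.n_sites):
            if not keep[i]:
                continue
            if genotyped[i] < 2:
                n_skipped += 1
                continue
            p = hwe_exact_pvalue(int(n_het[i]), int(n_hom_ref[i]), int(n_hom_alt[i]))
            if p < alpha:
                keep[i] = False
    if n_skipped:
        logger.info("hwe_filter: %d site/population pairs skipped (<2 genotyped)", n_skipped)
    logger.info("hwe_filter: %d -> %d sites", gm.n_sites, int(keep.sum()))
    return gm.take_sites(keep)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete observations; 0 when either has no variance."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window_bp: int = 50_000,
    r2_max: float = 0.5,
    step_sites: int = 5,
) -> GenotypeMatrix:
    """Greedy windowed LD pruning on alt-allele dosage.

    Windows of ``window_bp`` start at every ``step_sites``-th retained site
    (per chromosome); within a window, for any pair with genotype r-squared
    strictly above ``r2_max`` the later site is removed.  Passes repeat
    until stable, so the retained set contains no within-window pair above
    the threshold regardless of step granularity.  Deterministic.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    keep = np.ones(gm.n_sites, dtype=bool)
    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    changed = True
    while changed:
        changed = False
        for chrom in pd.unique(chroms):
            live = np.flatnonzero((chroms == chrom) & keep)
            for wstart in range(0, len(live), max(1, step_sites)):
                i0 = live[wstart]
                if not keep[i0]:
                    continue
                window = [j for j in live[wstart:] if keep[j] and pos[j] - pos[i0] <= window_bp]
                for a in range(len(window)):
                    ia = window[a]
                    if not keep[ia]:
                        continue
                    for ib in window[a + 1 :]:
                        if not keep[ib]:
                            continue
                        if _pairwise_r2(gm.calls[ia], gm.calls[ib]) > r2_max:
                            keep[ib] = False
                            changed = True
    logger.info("ld_prune: %d -> %d sites", gm.n_sites, int(keep.sum()))
    return gm.take_sites(keep)


def read_genetic_map(path) -> pd.DataFrame:
    """Read a genetic map TSV with columns chrom, pos (bp), cM."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "cM"])
    df["pos"] = df["pos"].astype(int)
    df["cM"] = df["cM"].astype(float)
    return df


def write_genetic_map(gmap: pd.DataFrame, path) -> None:
    gmap[["chrom", "pos", "cM"]].to_csv(path, sep="\t", header=False, index=False)


def read_bed_mask(path) -> pd.DataFrame:
    """Read a BED site mask (0-based half-open) into chrom/start/end."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    return df


def apply_bed_mask(gm: GenotypeMatrix, bed: pd.DataFrame) -> GenotypeMatrix:
    """Keep only sites falling inside BED intervals (converted to 1-based)."""
    keep = np.zeros(gm.n_sites, dtype=bool)
    pos = gm.sites["pos"].to_numpy()
    chroms = gm.sites["chrom"].to_numpy()
    for _, iv in bed.iterrows():
        keep |= (chroms == iv["chrom"]) & (pos > iv["start"]) & (pos <= iv["end"])
    logger.info("apply_bed_mask: %d -> %d sites", gm.n_sites, int(keep.sum()))
    return gm.take_sites(keep)
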