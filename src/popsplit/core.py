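"""Core containers: diploid genotype matrices and sample-to-population maps.

Genotypes are stored as alt-allele dosages in ``{0, 1, 2}`` with ``-1``
marking missing calls, in a sites x samples ``int8`` array.  Site metadata
(chromosome, 1-based position, REF/ALT alleles, phred-scaled QUAL) lives in
a parallel :class:`pandas.DataFrame`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "qual")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a panel of diploid samples.

    Attributes
    ----------
    samples:
        Ordered sample identifiers (columns of ``calls``).
    sites:
        Per-site records with columns ``chrom`` (label), ``pos`` (1-based
        bp, strictly increasing within a chromosome), ``ref``/``alt``
        (single bases) and ``qual`` (float, ``NaN`` when absent).
    calls:
        ``(n_sites, n_samples)`` int8 array of alt-allele dosages;
        ``-1`` encodes a missing genotype.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        missing_cols = set(SITE_COLUMNS) - set(self.sites.columns)
        if missing_cols:
            raise ValueError(f"sites table lacks columns {sorted(missing_cols)}")
        for _, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample {exc} not in matrix") from exc

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index, preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx],
            calls=self.calls[idx],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            sites=self.sites,
            calls=self.calls[:, idx],
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotype calls."""
        return (self.calls == MISSING).mean(axis=1)

    def alt_counts(self, sample_idx: np.ndarray | None = None):
        """Per-site alt-allele count and number of called chromosomes.

        Returns ``(alt, called)`` where ``alt[i]`` sums dosages over the
        selected samples at site ``i`` and ``called[i]`` is twice the number
        of non-missing genotypes there.
        """
        calls = self.calls if sample_idx is None else self.calls[:, sample_idx]
        called = 2 * (calls != MISSING).sum(axis=1)
        alt = np.where(calls == MISSING, 0, calls).sum(axis=1)
        return alt.astype(np.int64), called.astype(np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and self.sites[list(SITE_COLUMNS)].equals(other.sites[list(SITE_COLUMNS)])
        )


@dataclass
class PopulationMap:
    """Assignment of sample identifiers to population labels."""

    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        members = [s for s, p in self.assignments.items() if p == population]
        if not members:
            raise KeyError(f"population {population!r} not in map")
        return members

    def validate_against(self, gm: GenotypeMatrix, min_samples: int = 1) -> None:
        present = set(gm.samples)
        unknown = [s for s in self.assignments if s not in present]
        if unknown:
            raise ValueError(f"samples {unknown} mapped but absent from matrix")
        for pop in self.populations:
            n = len(self.samples_of(pop))
            if n < min_samples:
                raise ValueError(f"population {pop!r} has {n} < {min_samples} samples")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]] | Mapping[str, str]) -> "PopulationMap":
        if isinstance(pairs, Mapping):
            return cls(dict(pairs))
        return cls(dict(pairs))


def read_popmap(path) -> PopulationMap:
    """Read a two-column headerless TSV mapping sample to population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")
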