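"""Shared fixtures: hand-built toy matrices and session-scoped coalescent
simulations reused across test modules to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popsplit.core import GenotypeMatrix, PopulationMap
from popsplit.simulate import SimConfig, simulate_admixture_mosaic, simulate_split


def make_gm(calls: np.ndarray, samples=None, positions=None, quals=None, chrom="chr1"):
    """GenotypeMatrix from a (sites x samples) dosage array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    positions = positions if positions is not None else np.arange(1, n_sites + 1) * 100
    quals = quals if quals is not None else [50.0] * n_sites
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
            "qual": quals,
        }
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


@pytest.fixture
def toy_gm():
    """Six diploids, two populations, five fully-called sites."""
    calls = np.array(
        [
            [0, 1, 2, 0, 0, 1],
            [1, 1, 0, 2, 2, 2],
            [0, 0, 0, 0, 0, 1],
            [2, 2, 2, 2, 2, 2],
            [0, 0, 0, 0, 0, 0],
        ]
    )
    gm = make_gm(calls)
    popmap = PopulationMap(
        {"s0": "A", "s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "B"}
    )
    return gm, popmap


@pytest.fixture(scope="session")
def admixed_sim():
    """Recent 50/50 pulse between two long-diverged sources; the admixed
    population kept large so drift after the pulse is negligible."""
    cfg = SimConfig(
        populations={"ADM": 8, "SRC1": 8, "SRC2": 8},
        N_anc=1000,
        N={"ADM": 5000},
        split_times=4000.0,
        admixture_pulse=("ADM", "SRC1", "SRC2", 0.5, 10.0),
        mu=1e-7,
        n_loci=2500,
        seed=5,
    )
    return simulate_split(cfg)


@pytest.fixture(scope="session")
def treelike_sim():
    """Three populations related by a clean tree (no admixture)."""
    cfg = SimConfig(
        populations={"T": 8, "B": 8, "C": 8},
        N_anc=1000,
        split_times={"T": 2000.0, "B": 800.0, "C": 800.0},
        mu=1e-7,
        n_loci=1500,
        seed=6,
    )
    return simulate_split(cfg)


@pytest.fixture(scope="session")
def panmictic_sim():
    """One population arbitrarily relabeled into three groups."""
    cfg = SimConfig(
        populations={"P": 18},
        N_anc=1000,
        split_times=1.0,
        mu=1e-7,
        n_loci=1500,
        seed=7,
    )
    gm, _ = simulate_split(cfg)
    labels = {}
    for i, s in enumerate(gm.samples):
        labels[s] = ["G1", "G2", "G3"][i % 3]
    return gm, PopulationMap(labels)


MOSAIC_G = 50.0


def mosaic_config(seed: int) -> SimConfig:
    return SimConfig(
        populations={"ADM": 20, "SRC1": 15, "SRC2": 15},
        N_anc=2000,
        split_times=8000.0,
        admixture_pulse=("ADM", "SRC1", "SRC2", 0.5, MOSAIC_G),
        mu=1.2e-8,
        recombination_morgans=1.0,
        mosaic_sites=900,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mosaic_ds():
    """Admixture mosaic with pulse age 50 generations."""
    return simulate_admixture_mosaic(mosaic_config(42))


@pytest.fixture(scope="session")
def twopop_sim():
    """Unequal-size two-population split used by SFS/fit unit tests."""
    cfg = SimConfig(
        populations={"EUR": 8, "ENA": 8},
        N_anc=1000,
        N={"EUR": 1200, "ENA": 700},
        split_times=1000.0,
        mu=1e-7,
        n_loci=2000,
        seed=11,
    )
    return simulate_split(cfg)
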