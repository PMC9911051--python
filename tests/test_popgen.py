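"""Spectra and diversity estimators against hand/brute-force oracles."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from popsplit.core import MISSING, PopulationMap
from popsplit.popgen import (
    FoldedSFS,
    diversity_from_sfs,
    diversity_stats,
    fold_joint,
    folded_sfs,
    harmonic,
    joint_folded_sfs,
    round_half_away,
    summarize_diversity,
    weir_cockerham_fst,
)

from .conftest import make_gm


def _pm_single(gm, pop="P"):
    return PopulationMap({s: pop for s in gm.samples})


# ---------------------------------------------------------------------------
# folded SFS


def test_folded_sfs_folding_arithmetic():
    # 3 diploids: dosages (0,1,2) -> alt count 3/6 -> folded class 3
    # second site derived count 5/6 -> folded class 1; third monomorphic
    calls = np.array([[0, 1, 2], [2, 2, 1], [0, 0, 0]], dtype=np.int8)
    gm = make_gm(calls)
    sfs = folded_sfs(gm, _pm_single(gm), "P")
    assert sfs.n == 6
    assert sfs.counts[3] == pytest.approx(1.0)
    assert sfs.counts[1] == pytest.approx(1.0)
    assert sfs.counts[0] == pytest.approx(1.0)  # monomorphic class
    assert sfs.S == pytest.approx(2.0)


def test_folded_sfs_monomorphic_only():
    gm = make_gm(np.zeros((100, 4), dtype=np.int8))
    sfs = folded_sfs(gm, _pm_single(gm), "P")
    assert sfs.S == 0.0
    assert sfs.counts[0] == 100.0


def test_folded_sfs_projection_hypergeometric():
    # one site, 3 diploids, alt count 2 of 6; project to n=4:
    # P(k alt of 4 | 2 of 6) = C(2,k) C(4,4-k) / C(6,4), folded
    calls = np.array([[1, 1, 0]], dtype=np.int8)
    gm = make_gm(calls)
    sfs = folded_sfs(gm, _pm_single(gm), "P", projection_n=4)
    def hyp(k):
        return math.comb(2, k) * math.comb(4, 4 - k) / math.comb(6, 4)
    assert sfs.counts[0] == pytest.approx(hyp(0))
    assert sfs.counts[1] == pytest.approx(hyp(1))
    assert sfs.counts[2] == pytest.approx(hyp(2))
    assert sfs.counts.sum() == pytest.approx(1.0)


def test_folded_sfs_missing_data_site_dropped_below_projection():
    calls = np.array([[1, MISSING, MISSING], [1, 0, 0]], dtype=np.int8)
    gm = make_gm(calls)
    sfs = folded_sfs(gm, _pm_single(gm), "P", projection_n=4)
    assert sfs.L == 1.0  # first site has only 2 callable chromosomes


def test_folded_sfs_segregating_classes_match_diversity_S(twopop_sim):
    gm, pm = twopop_sim
    sfs = folded_sfs(gm, pm, "EUR")
    st = diversity_stats(gm, pm, "EUR")
    assert sfs.S == pytest.approx(st.S)


# ---------------------------------------------------------------------------
# joint SFS


def test_fold_joint_merge_convention():
    n1 = n2 = 2
    unfolded = np.zeros((3, 3))
    unfolded[2, 0] = 5.0  # total 2 = partner total (0,2): tie -> lex smaller
    unfolded[0, 2] = 3.0
    unfolded[2, 2] = 1.0  # partner (0,0)
    folded = fold_joint(unfolded)
    assert folded[0, 2] == 8.0
    assert folded[2, 0] == 0.0
    assert folded[0, 0] == 1.0


def test_fold_joint_total_mass_preserved():
    rng = np.random.default_rng(3)
    grid = rng.random((5, 7))
    assert fold_joint(grid).sum() == pytest.approx(grid.sum())


def test_joint_sfs_hand_tally():
    # pops A, B of 2 diploids each; 5 sites
    calls = np.array(
        [
            [0, 1, 0, 0],  # A alt 1/4, B alt 0/4 -> (1, 0)
            [2, 2, 0, 0],  # A fixed alt, B absent -> (4,0) folds to (0,4)? no:
            #   (4,0) total 4 = partner (0,4) total 4 tie -> lex smaller (0,4)
            [1, 1, 1, 1],  # (2,2) self-partner under fold
            [0, 0, 0, 1],  # (0,1)
            [2, 2, 2, 2],  # (4,4) -> folds onto (0,0)
        ],
        dtype=np.int8,
    )
    gm = make_gm(calls)
    pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    sfs = joint_folded_sfs(gm, pm, "A", "B")
    expected = np.zeros((5, 5))
    expected[1, 0] = 1
    expected[0, 4] = 1
    expected[2, 2] = 1
    expected[0, 1] = 1
    expected[0, 0] = 1
    assert np.allclose(sfs.counts, expected)
    assert sfs.L == 5.0


def test_joint_sfs_identical_population_concentrates_on_diagonal(twopop_sim):
    gm, _ = twopop_sim
    # split EUR's 8 samples into two "populations" of 4: frequencies are
    # correlated draws from the same population -> mass hugs the diagonal
    labels = {f"EUR_{i}": ("X" if i < 4 else "Y") for i in range(8)}
    pm = PopulationMap(labels)
    sub = gm.take_samples(list(labels))
    sfs = joint_folded_sfs(sub, pm, "X", "Y")
    grid = sfs.counts.copy()
    grid[0, 0] = 0.0
    i, j = np.indices(grid.shape)
    near = np.abs(i - j) <= 2
    assert grid[near].sum() / grid.sum() > 0.8


def test_joint_sfs_overlapping_populations_error(toy_gm):
    gm, _ = toy_gm
    pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    pm.assignments["s1"] = "A"
    pm2 = PopulationMap({"s0": "A", "s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "B"})
    with pytest.raises(ValueError):
        # same samples under both labels via a map that aliases them
        joint_folded_sfs(gm, PopulationMap({"s0": "A", "s1": "B"}), "A", "A")


# ---------------------------------------------------------------------------
# diversity


def test_pi_two_haploids_hand_count():
    # one diploid (2 haploids), het at 1 site of 100 -> pi = 0.01
    calls = np.zeros((100, 1), dtype=np.int8)
    calls[0, 0] = 1
    gm = make_gm(calls)
    st = diversity_stats(gm, _pm_single(gm), "P")
    assert st.pi == pytest.approx(0.01)


def test_theta_w_harmonic_hand_sum():
    # 5 diploids (n=10), 5 segregating singleton sites of 1000
    calls = np.zeros((1000, 5), dtype=np.int8)
    for i in range(5):
        calls[i, i] = 1
    gm = make_gm(calls)
    st = diversity_stats(gm, _pm_single(gm), "P")
    a9 = sum(Fraction(1, i) for i in range(1, 10))
    assert st.theta_w == pytest.approx(5 / (float(a9) * 1000), rel=1e-12)


def test_tajima_d_zero_when_numerator_zero():
    gm = make_gm(np.zeros((50, 4), dtype=np.int8))
    st = diversity_stats(gm, _pm_single(gm), "P")
    assert st.tajima_d == 0.0
    assert st.S == 0


def test_diversity_errors():
    gm = make_gm(np.full((2, 3), MISSING, dtype=np.int8))
    with pytest.raises(ValueError):
        diversity_stats(gm, _pm_single(gm), "P")


def test_sfs_and_genotype_paths_agree(twopop_sim):
    """pi and theta from the folded SFS equal the direct genotype-based
    computation on fully called data (two independent code paths)."""
    gm, pm = twopop_sim
    st = diversity_stats(gm, pm, "ENA")
    sfs = folded_sfs(gm, pm, "ENA")
    pi2, theta2 = diversity_from_sfs(sfs)
    assert pi2 == pytest.approx(st.pi, rel=1e-10)
    assert theta2 == pytest.approx(st.theta_w, rel=1e-10)


# ---------------------------------------------------------------------------
# F_st


def test_fst_fixed_difference_is_one():
    calls = np.array([[0, 0, 2, 2], [0, 0, 2, 2]], dtype=np.int8)
    gm = make_gm(calls)
    pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    res = weir_cockerham_fst(gm, pm, "A", "B")
    assert res.fst == pytest.approx(1.0)


def test_fst_identical_populations_not_positive():
    """Byte-identical samples carry no among-population signal: the
    estimator's a component is non-positive (slightly negative in finite
    samples, as the 1984 moment estimator corrects for sampling noise
    that is absent here), never positive."""
    block = np.array([[0, 1], [2, 1], [1, 1]], dtype=np.int8)
    calls = np.hstack([block, block])
    gm = make_gm(calls)
    pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    res = weir_cockerham_fst(gm, pm, "A", "B")
    assert res.a <= 0.0
    assert res.fst <= 0.0


def test_fst_hand_evaluated_components():
    # popA genotypes [0, 1], popB [2, 2] at one site: exact value 2/3
    calls = np.array([[0, 1, 2, 2]], dtype=np.int8)
    gm = make_gm(calls)
    pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    res = weir_cockerham_fst(gm, pm, "A", "B")
    assert res.fst == pytest.approx(2.0 / 3.0, rel=1e-12)
    assert res.a == pytest.approx(0.25, rel=1e-12)
    assert res.b == pytest.approx(0.0, abs=1e-12)
    assert res.c == pytest.approx(0.125, rel=1e-12)


def test_fst_undefined_without_polymorphism():
    gm = make_gm(np.zeros((3, 4), dtype=np.int8))
    pm = PopulationMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
    with pytest.raises(ValueError, match="undefined"):
        weir_cockerham_fst(gm, pm, "A", "B")


# ---------------------------------------------------------------------------
# reporting


def test_round_half_away():
    assert round_half_away(0.1675, 3) == 0.168
    assert round_half_away(-0.1675, 3) == -0.168
    assert round_half_away(0.165, 2) == 0.17


def test_summarize_diversity_group_means(toy_gm):
    gm, pm = toy_gm
    stats = [diversity_stats(gm, pm, p) for p in ("A", "B")]
    table = summarize_diversity(stats, groups={"all": ["A", "B"]})
    mean_row = table[table["population"] == "mean(all)"].iloc[0]
    manual = 100 * np.mean([s.pi for s in stats])
    assert mean_row["pi_pct"] == round_half_away(manual, 2)
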