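"""Expected-SFS engine, composite likelihood, LRT, unit conversion and
block bootstrap."""

from __future__ import annotations

import math

import numpy as np
import pytest

from popsplit.core import PopulationMap
from popsplit.demography import (
    EngineSettings,
    FitBounds,
    FitResult,
    GASettings,
    SplitModel,
    block_bootstrap,
    convert_units,
    expected_joint_sfs,
    fit_split_model,
    likelihood_ratio_test,
    poisson_composite_loglik,
    site_blocks,
)
from popsplit.popgen import JointSFS, equilibrium_folded_expectation, joint_folded_sfs


# ---------------------------------------------------------------------------
# model container


def test_split_model_family_constraints():
    with pytest.raises(ValueError):
        SplitModel("no_migration", 1, 1, 0.5, m12=1.0)
    with pytest.raises(ValueError):
        SplitModel("unidirectional", 1, 1, 0.5, m12=1.0, m21=1.0)
    with pytest.raises(ValueError):
        SplitModel("bidirectional", 1, -1, 0.5)
    m = SplitModel("bidirectional", 1.5, 0.5, 0.3, m12=1.0, m21=2.0)
    assert SplitModel.from_vector("bidirectional", m.to_vector()) == m


# ---------------------------------------------------------------------------
# expected SFS engine


def test_expected_sfs_equilibrium_limit_marginal():
    """T -> 0 with nu = 1 collapses to one panmictic population: the
    combined marginal spectrum follows the folded 1/i law."""
    exp = expected_joint_sfs(
        SplitModel("no_migration", 1, 1, 1e-3), 6, 6,
        EngineSettings(n_genealogies=3000, seed=5),
    )
    n = 12
    marg = np.zeros(n // 2 + 1)
    for i in range(7):
        for j in range(7):
            k = i + j
            marg[min(k, n - k)] += exp.counts[i, j]
    obs = marg[1:]
    law = equilibrium_folded_expectation(n) * obs.sum()
    assert np.max(np.abs(obs - law) / law) < 0.1


def test_expected_sfs_symmetric_model_is_symmetric():
    exp = expected_joint_sfs(
        SplitModel("bidirectional", 1, 1, 0.5, m12=1.0, m21=1.0), 6, 6,
        EngineSettings(n_genealogies=3000, seed=9),
    )
    g = exp.counts
    asym = np.abs(g - g.T).sum() / g.sum()
    assert asym < 0.1


def test_expected_sfs_shared_polymorphism_shrinks_with_depth():
    eng = EngineSettings(n_genealogies=1500, seed=11)
    shallow = expected_joint_sfs(SplitModel("no_migration", 1, 1, 0.05), 6, 6, eng)
    deep = expected_joint_sfs(SplitModel("no_migration", 1, 1, 2.5), 6, 6, eng)

    def shared_fraction(sfs):
        g = sfs.counts.copy()
        g[0, 0] = 0.0
        shared = g[1:, 1:].sum()
        return shared / g.sum()

    assert shared_fraction(deep) < shared_fraction(shallow)


def test_zero_migration_families_reproduce_no_migration_engine_exactly():
    eng = EngineSettings(n_genealogies=300, seed=13)
    base = expected_joint_sfs(SplitModel("no_migration", 1.2, 0.8, 0.4), 5, 5, eng)
    uni = expected_joint_sfs(
        SplitModel("unidirectional", 1.2, 0.8, 0.4, m12=0.0), 5, 5, eng
    )
    bi = expected_joint_sfs(
        SplitModel("bidirectional", 1.2, 0.8, 0.4, m12=0.0, m21=0.0), 5, 5, eng
    )
    assert np.array_equal(base.counts, uni.counts)
    assert np.array_equal(base.counts, bi.counts)


# ---------------------------------------------------------------------------
# composite likelihood


def _toy_pair():
    obs = JointSFS(n1=2, n2=2, counts=np.array(
        [[0.0, 4, 2], [3, 5, 1], [2, 1, 0]]), L=18)
    exp = JointSFS(n1=2, n2=2, counts=np.array(
        [[0.5, 2.0, 1.0], [1.5, 2.5, 0.5], [1.0, 0.5, 0.2]]), L=1)
    return obs, exp


def test_loglik_matches_hand_summation():
    obs, exp = _toy_pair()
    ll, theta = poisson_composite_loglik(obs, exp)
    mask = obs.mask
    o = obs.counts[mask]
    e = exp.counts[mask]
    theta_hand = o.sum() / e.sum()
    ll_hand = sum(
        oi * math.log(theta_hand * ei) - theta_hand * ei
        for oi, ei in zip(o, e)
        if oi > 0
    ) - sum(theta_hand * ei for oi, ei in zip(o, e) if oi == 0)
    assert theta == pytest.approx(theta_hand, rel=1e-12)
    assert ll == pytest.approx(ll_hand, rel=1e-12)


def test_theta_hat_is_the_maximizer():
    obs, exp = _toy_pair()
    _, theta = poisson_composite_loglik(obs, exp)

    def ll_at(t):
        mask = obs.mask
        o, e = obs.counts[mask], exp.counts[mask]
        return np.sum(o * np.log(t * e + 1e-300)) - t * e.sum()

    assert ll_at(theta) >= ll_at(theta * 1.05)
    assert ll_at(theta) >= ll_at(theta * 0.95)


def test_loglik_exact_scaling_recovers_theta():
    _, exp = _toy_pair()
    scaled = JointSFS(n1=2, n2=2, counts=7.5 * exp.counts, L=1)
    ll, theta = poisson_composite_loglik(scaled, exp)
    assert theta == pytest.approx(7.5, rel=1e-12)


def test_loglik_all_zero_observed_boundary():
    _, exp = _toy_pair()
    zero = JointSFS(n1=2, n2=2, counts=np.zeros((3, 3)), L=0)
    ll, theta = poisson_composite_loglik(zero, exp)
    assert (ll, theta) == (0.0, 0.0)


def test_loglik_shape_mismatch():
    obs, _ = _toy_pair()
    other = JointSFS(n1=2, n2=3, counts=np.zeros((3, 4)), L=1)
    with pytest.raises(ValueError):
        poisson_composite_loglik(obs, other)


# ---------------------------------------------------------------------------
# LRT


def _fake_fit(family, loglik):
    kwargs = {}
    if family in ("unidirectional", "bidirectional"):
        kwargs["m12"] = 0.1
    if family == "bidirectional":
        kwargs["m21"] = 0.1
    return FitResult(
        model=SplitModel(family, 1, 1, 0.5, **kwargs), theta_hat=1.0, loglik=loglik
    )


def test_lrt_identical_logliks():
    res = likelihood_ratio_test(_fake_fit("no_migration", -10.0), _fake_fit("bidirectional", -10.0))
    assert res.statistic == 0.0
    assert res.p_value == 1.0
    assert res.df == 2


def test_lrt_chi2_closed_form_df2():
    res = likelihood_ratio_test(_fake_fit("no_migration", -10.0), _fake_fit("bidirectional", -7.0))
    assert res.statistic == pytest.approx(6.0)
    assert res.p_value == pytest.approx(math.exp(-3.0), rel=1e-12)


def test_lrt_rejects_non_nested():
    with pytest.raises(ValueError):
        likelihood_ratio_test(_fake_fit("bidirectional", -5.0), _fake_fit("no_migration", -4.0))


# ---------------------------------------------------------------------------
# unit conversion


def test_convert_units_arithmetic():
    fit = FitResult(
        model=SplitModel("unidirectional", 2.0, 1.0, 1.0, m12=4.0),
        theta_hat=4.0,
        loglik=0.0,
    )
    conv = convert_units(fit, mu=4e-9, L=1_000_000, generation_time=1.0)
    assert conv["N_anc"] == pytest.approx(250.0)
    assert conv["N1"] == pytest.approx(500.0)
    assert conv["T_years"] == pytest.approx(500.0)
    assert conv["m12_per_gen"] == pytest.approx(4.0 / 500.0)


def test_convert_units_round_trip():
    fit = FitResult(
        model=SplitModel("bidirectional", 1.7, 0.3, 0.42, m12=1.1, m21=0.2),
        theta_hat=37.5,
        loglik=0.0,
    )
    conv = convert_units(fit, mu=4e-9, L=5e5, generation_time=2.0)
    n_anc = conv["N_anc"]
    assert conv["N1"] / n_anc == pytest.approx(1.7, rel=1e-12)
    assert conv["T_years"] / (2 * n_anc * 2.0) == pytest.approx(0.42, rel=1e-12)
    assert conv["m12_per_gen"] * 2 * n_anc == pytest.approx(1.1, rel=1e-12)


def test_convert_units_requires_positive_theta():
    fit = FitResult(model=SplitModel("no_migration", 1, 1, 0.5), theta_hat=0.0, loglik=0.0)
    with pytest.raises(ValueError):
        convert_units(fit, mu=4e-9, L=1e6)


# ---------------------------------------------------------------------------
# fitting


def test_fit_is_deterministic_for_fixed_seed(twopop_sim):
    gm, pm = twopop_sim
    obs = joint_folded_sfs(gm, pm, "EUR", "ENA", 6, 6)
    eng = EngineSettings(n_genealogies=60, seed=77)
    ga = GASettings(population=6, generations=3, local_maxiter=20)
    f1 = fit_split_model(obs, "no_migration", seed=5, engine=eng, ga=ga)
    f2 = fit_split_model(obs, "no_migration", seed=5, engine=eng, ga=ga)
    assert f1.model == f2.model
    assert f1.loglik == f2.loglik
    assert f1.theta_hat == f2.theta_hat


def test_nested_family_fit_consistency(twopop_sim):
    """On data generated without migration, adding migration cannot be
    (significantly) better: the LRT must not reject the simple model."""
    gm, pm = twopop_sim
    obs = joint_folded_sfs(gm, pm, "EUR", "ENA", 6, 6)
    eng = EngineSettings(n_genealogies=400, seed=321)
    ga = GASettings(local_maxiter=40)
    null = fit_split_model(obs, "no_migration", seed=1, engine=eng, ga=ga,
                           start=SplitModel("no_migration", 1, 1, 0.5), method="local")
    alt = fit_split_model(
        obs, "bidirectional", seed=1, engine=eng, ga=ga,
        start=SplitModel(
            "bidirectional",
            null.model.nu1, null.model.nu2, null.model.T,
            m12=1e-3, m21=1e-3,
        ),
        method="local",
    )
    res = likelihood_ratio_test(null, alt)
    assert res.p_value > 0.05


# ---------------------------------------------------------------------------
# block bootstrap


def test_site_blocks_partition(twopop_sim):
    gm, _ = twopop_sim
    blocks = site_blocks(gm, 10_000)
    total = sum(len(b) for b in blocks)
    assert total == gm.n_sites
    flat = np.concatenate(blocks)
    assert len(np.unique(flat)) == gm.n_sites


def test_bootstrap_identity_choices_reproduce_original(twopop_sim):
    gm, pm = twopop_sim
    blocks = site_blocks(gm, 10_000)
    ident = np.arange(len(blocks))[None, :]
    reps = block_bootstrap(gm, pm, "EUR", "ENA", 8, 8, n_reps=1,
                           block_choices=ident)
    direct = joint_folded_sfs(gm, pm, "EUR", "ENA", 8, 8)
    assert np.allclose(reps[0].counts, direct.counts)
    assert reps[0].L == direct.L


def test_bootstrap_site_count_expectation(twopop_sim):
    gm, pm = twopop_sim
    reps = block_bootstrap(gm, pm, "EUR", "ENA", 8, 8, n_reps=60, seed=3)
    totals = [r.L for r in reps]
    assert np.mean(totals) == pytest.approx(gm.n_sites, rel=0.05)


def test_bootstrap_theta_sd_matches_resampling_theory(twopop_sim):
    """SD of theta-hat across replicates agrees with the analytic
    with-replacement resampling variance of block totals."""
    gm, pm = twopop_sim
    exp = expected_joint_sfs(
        SplitModel("no_migration", 1.2, 0.7, 0.5), 8, 8,
        EngineSettings(n_genealogies=400, seed=17),
    )
    reps = block_bootstrap(gm, pm, "EUR", "ENA", 8, 8, n_reps=150, seed=29)
    thetas = [poisson_composite_loglik(r, exp)[1] for r in reps]
    blocks = site_blocks(gm, 10_000)
    sub = [gm.take_sites(b) for b in blocks]
    block_tot = np.array(
        [joint_folded_sfs(s, pm, "EUR", "ENA", 8, 8).counts[exp.mask].sum() for s in sub]
    )
    # theta_rep = sum of B with-replacement draws / sum(exp)
    mask_sum = exp.counts[exp.mask].sum()
    pred_sd = np.sqrt(len(blocks) * block_tot.var()) / mask_sum
    assert np.std(thetas, ddof=1) == pytest.approx(pred_sd, rel=0.3)


def test_bootstrap_parameter_sds_from_replicates(twopop_sim):
    gm, pm = twopop_sim
    obs = joint_folded_sfs(gm, pm, "EUR", "ENA", 6, 6)
    eng = EngineSettings(n_genealogies=80, seed=5)
    fit = fit_split_model(
        obs, "no_migration", seed=2, engine=eng,
        ga=GASettings(local_maxiter=25),
        start=SplitModel("no_migration", 1.2, 0.7, 0.5), method="local",
    )
    reps = block_bootstrap(gm, pm, "EUR", "ENA", 6, 6, n_reps=3, seed=4)
    from popsplit.demography import bootstrap_parameter_sds

    sds = bootstrap_parameter_sds(
        fit, reps, seed=9, engine=eng, ga=GASettings(local_maxiter=15)
    )
    assert set(sds) == {"nu1", "nu2", "T", "theta"}
    assert all(v >= 0 for v in sds.values())
    assert fit.sd == sds
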