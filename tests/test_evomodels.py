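"""Trait-evolution model means, covariances, likelihoods, fits, simulation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import elevolve as ev
from elevolve.evomodels import ModelContext

from conftest import mixed_regimes, random_tree


def random_params(model, rng):
    if model == "WN":
        return ev.EvoParams("WN", mu=rng.normal(), sigma2=rng.uniform(0.5, 3))
    if model == "BM1":
        return ev.EvoParams("BM1", x0=rng.normal(), sigma2=rng.uniform(0.1, 2))
    if model == "BMM":
        return ev.EvoParams(
            "BMM", x0=rng.normal(),
            sigma2_low=rng.uniform(0.1, 2), sigma2_high=rng.uniform(0.1, 2),
        )
    if model == "OU1":
        return ev.EvoParams(
            "OU1", alpha=rng.uniform(0.05, 1), sigma2=rng.uniform(0.5, 3),
            theta=rng.normal(),
        )
    return ev.EvoParams(
        "OUM", alpha=rng.uniform(0.05, 1), sigma2=rng.uniform(0.5, 3),
        theta_low=rng.normal(), theta_high=rng.normal(),
    )


@pytest.mark.parametrize("model", ev.MODELS)
def test_loglik_matches_dense_mvn(model):
    """Own Cholesky-based density vs scipy's dense MVN on random inputs."""
    rng = np.random.default_rng(hash(model) % 2**31)
    for _ in range(20):
        tree = random_tree(rng, int(rng.integers(4, 9)))
        smap, reg = mixed_regimes(tree, rng)
        params = random_params(model, rng)
        se = rng.uniform(0.0, 0.5, tree.n_tips)
        data = ev.simulate_traits(model, tree, smap, params, se, int(rng.integers(2**31)))
        ll = ev.model_loglik(tree, smap, params, data)
        mu = ev.model_mean(tree, smap, params)
        V = ev.model_covariance(tree, smap, params, data)
        assert ll == pytest.approx(
            multivariate_normal.logpdf(data.mean, mu, V), abs=1e-8
        )


def test_wn_zero_se_is_independent_normals(tree5):
    params = ev.EvoParams("WN", mu=1.5, sigma2=2.0)
    rng = np.random.default_rng(0)
    y = rng.normal(size=tree5.n_tips)
    data = ev.TraitData(tree5.tip_labels, y, np.zeros(tree5.n_tips))
    ll = ev.model_loglik(tree5, None, params, data)
    direct = sum(
        -0.5 * np.log(2 * np.pi * 2.0) - (v - 1.5) ** 2 / (2 * 2.0) for v in y
    )
    assert ll == pytest.approx(direct, abs=1e-10)


def test_zero_se_identity(tree5):
    rng = np.random.default_rng(1)
    smap, reg = mixed_regimes(tree5, rng)
    params = ev.EvoParams("BM1", x0=0.0, sigma2=1.0)
    y = rng.normal(size=tree5.n_tips)
    d0 = ev.TraitData(tree5.tip_labels, y, np.zeros(tree5.n_tips))
    assert ev.model_loglik(tree5, None, params, d0) == pytest.approx(
        ev.model_loglik(tree5, smap, params, d0), abs=1e-12
    )


def test_ou_small_alpha_matches_bm(tree5):
    p_ou = ev.EvoParams("OU1", alpha=1e-8, sigma2=1.3, theta=0.7)
    p_bm = ev.EvoParams("BM1", x0=0.7, sigma2=1.3)
    V_ou = ev.model_covariance(tree5, None, p_ou)
    V_bm = ev.model_covariance(tree5, None, p_bm)
    assert np.max(np.abs(V_ou - V_bm)) / np.max(V_bm) < 1e-4


def test_bmm_collapses_to_bm1(tree5):
    rng = np.random.default_rng(2)
    smap, _ = mixed_regimes(tree5, rng)
    p_bmm = ev.EvoParams("BMM", x0=0.0, sigma2_low=1.7, sigma2_high=1.7)
    p_bm = ev.EvoParams("BM1", x0=0.0, sigma2=1.7)
    assert np.allclose(
        ev.model_covariance(tree5, smap, p_bmm),
        ev.model_covariance(tree5, None, p_bm),
    )


def test_oum_equal_optima_collapses_to_ou1(tree5):
    rng = np.random.default_rng(3)
    smap, _ = mixed_regimes(tree5, rng)
    p = ev.EvoParams("OUM", alpha=0.3, sigma2=1.0, theta_low=2.5, theta_high=2.5)
    assert np.allclose(ev.model_mean(tree5, smap, p), 2.5)


def test_oum_large_alpha_limit():
    """Strong pull: each tip's expectation is its terminal regime's optimum."""
    rng = np.random.default_rng(4)
    tree = random_tree(rng, 10, height=30.0)
    smap, reg = mixed_regimes(tree, rng)
    p = ev.EvoParams("OUM", alpha=1e3, sigma2=1.0, theta_low=70.16, theta_high=23.65)
    mu = ev.model_mean(tree, smap, p)
    states = smap.tip_states(tree)
    expect = np.where(states == ev.LOW, 70.16, 23.65)
    assert np.allclose(mu, expect, atol=1e-6)


def test_oum_mean_matches_quadrature():
    rng = np.random.default_rng(5)
    tree = random_tree(rng, 6, height=30.0)
    smap, _ = mixed_regimes(tree, rng)
    alpha = 0.1
    p = ev.EvoParams("OUM", alpha=alpha, sigma2=2.0, theta_low=1.0, theta_high=5.0)
    mu = ev.model_mean(tree, smap, p)
    ctx = ModelContext(tree, smap, None)
    theta = {ev.LOW: 1.0, ev.HIGH: 5.0}
    for i, segs in enumerate(ctx.tip_segments):
        val = theta[ctx.origin_state] * np.exp(-alpha * ctx.T)
        for t0, t1, s in segs:
            ts = np.linspace(t0, t1, 4001)
            val += np.trapezoid(theta[s] * alpha * np.exp(-alpha * (ctx.T - ts)), ts)
        assert mu[i] == pytest.approx(val, abs=1e-6)


def test_oum_covariance_matches_path_simulation():
    """Empirical covariance of exactly simulated OU paths down a 4-tip tree."""
    rng = np.random.default_rng(6)
    tree = random_tree(rng, 4, height=5.0)
    smap, _ = mixed_regimes(tree, rng)
    alpha, s2 = 0.5, 1.0
    p = ev.EvoParams("OUM", alpha=alpha, sigma2=s2, theta_low=0.0, theta_high=3.0)
    V = ev.model_covariance(tree, smap, p)
    mu = ev.model_mean(tree, smap, p)
    theta = {ev.LOW: 0.0, ev.HIGH: 3.0}
    n_paths = 60_000
    ctx = ModelContext(tree, smap, None)
    x_root = np.full(n_paths, theta[ctx.origin_state])  # root pinned to optimum
    node_vals = {0: x_root}
    for node in range(1, tree.n_nodes):
        x = node_vals[tree.parent[node]].copy()
        segs = smap.segments[node]
        for dur, s in segs:
            if dur <= 0:
                continue
            e = np.exp(-alpha * dur)
            sd = np.sqrt(s2 / (2 * alpha) * (1 - e**2))
            x = theta[s] + (x - theta[s]) * e + sd * rng.standard_normal(n_paths)
        node_vals[node] = x
    tipX = np.column_stack([node_vals[t] for t in tree.tips])
    emp_mu = tipX.mean(axis=0)
    emp_V = np.cov(tipX.T)
    assert np.max(np.abs(emp_mu - mu)) < 0.05
    assert np.max(np.abs(emp_V - V)) < 0.05


def test_simulation_moments(tree5):
    rng = np.random.default_rng(7)
    smap, _ = mixed_regimes(tree5, rng)
    p = ev.EvoParams("BM1", x0=1.0, sigma2=0.5)
    draws = np.array(
        [
            ev.simulate_traits("BM1", tree5, None, p, 0.2, seed=s).mean
            for s in range(4000)
        ]
    )
    mu = ev.model_mean(tree5, None, p)
    data = ev.TraitData(tree5.tip_labels, mu, np.full(tree5.n_tips, 0.2))
    V = ev.model_covariance(tree5, None, p, data)
    assert np.max(np.abs(draws.mean(axis=0) - mu)) < 0.1
    assert np.max(np.abs(np.cov(draws.T) - V)) < 0.35


def test_simulation_noiseless_and_deterministic(tree5):
    p = ev.EvoParams("BM1", x0=2.0, sigma2=1e-12)
    d = ev.simulate_traits("BM1", tree5, None, p, 0.0, seed=3)
    assert np.allclose(d.mean, 2.0, atol=1e-4)
    d1 = ev.simulate_traits("BM1", tree5, None, ev.EvoParams("BM1", x0=0, sigma2=1), 0.3, seed=9)
    d2 = ev.simulate_traits("BM1", tree5, None, ev.EvoParams("BM1", x0=0, sigma2=1), 0.3, seed=9)
    assert np.array_equal(d1.mean, d2.mean)


def test_nesting_of_likelihoods():
    rng = np.random.default_rng(8)
    tree = random_tree(rng, 40, height=30.0)
    smap, _ = mixed_regimes(tree, rng)
    p = ev.EvoParams("OUM", alpha=0.2, sigma2=2.0, theta_low=0.0, theta_high=4.0)
    data = ev.simulate_traits("OUM", tree, smap, p, 0.3, seed=11)
    fits = ev.fit_all_models(tree, smap, data)
    assert fits["OUM"].loglik >= fits["OU1"].loglik - 1e-4
    assert fits["BMM"].loglik >= fits["BM1"].loglik - 1e-4


def test_unit_rescaling_invariance():
    """Tree x c with (alpha, sigma2)/c leaves the OU likelihood unchanged."""
    rng = np.random.default_rng(9)
    tree = random_tree(rng, 12, height=10.0)
    c = 3.0
    scaled = ev.Tree(tree.parent, tree.lengths * c, tree.labels, tree.root_length * c)
    y = rng.normal(size=tree.n_tips)
    data = ev.TraitData(tree.tip_labels, y, np.zeros(tree.n_tips))
    p1 = ev.EvoParams("OU1", alpha=0.4, sigma2=1.5, theta=0.2)
    p2 = ev.EvoParams("OU1", alpha=0.4 / c, sigma2=1.5 / c, theta=0.2)
    assert ev.model_loglik(tree, None, p1, data) == pytest.approx(
        ev.model_loglik(scaled, None, p2, data), abs=1e-10
    )


def test_bm1_recovery():
    rng = np.random.default_rng(10)
    hits = 0
    n = 15
    for _ in range(n):
        tree = random_tree(rng, 100, height=30.0)
        p = ev.EvoParams("BM1", x0=0.0, sigma2=1.0)
        data = ev.simulate_traits("BM1", tree, None, p, 0.0, int(rng.integers(2**31)))
        fit = ev.fit_evo_model("BM1", tree, None, data)
        hits += 0.7 <= fit.params.sigma2 <= 1.3
    assert hits >= 0.8 * n


def test_degenerate_constant_trait(tree5):
    data = ev.TraitData(tree5.tip_labels, np.full(tree5.n_tips, 3.0), np.zeros(tree5.n_tips))
    with pytest.raises((ValueError, RuntimeError)):
        ev.fit_evo_model("WN", tree5, None, data)


def test_oum_without_map_errors(tree5):
    p = ev.EvoParams("OUM", alpha=0.2, sigma2=1.0, theta_low=0.0, theta_high=1.0)
    with pytest.raises(ValueError):
        ev.model_mean(tree5, None, p)


def test_ou_requires_ultrametric():
    t = ev.parse_newick("((A:1,B:2):1,C:2):0;")
    p = ev.EvoParams("OU1", alpha=0.2, sigma2=1.0, theta=0.0)
    with pytest.raises(ValueError, match="ultrametric"):
        ev.model_covariance(t, None, p)


def test_aicc_consistency_of_fit(tree5):
    rng = np.random.default_rng(12)
    data = ev.simulate_traits(
        "BM1", tree5, None, ev.EvoParams("BM1", x0=0, sigma2=1), 0.1, seed=13
    )
    fit = ev.fit_evo_model("BM1", tree5, None, data)
    assert fit.aicc == pytest.approx(ev.aicc(fit.loglik, fit.k, fit.n_species))
    assert fit.k == 2
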