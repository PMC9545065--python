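"""Regime assignment, Mk likelihood/fitting, and stochastic character maps."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import elevolve as ev
from elevolve.regimes import (
    HIGH,
    LOW,
    _sample_path_rejection,
    _sample_path_uniformization,
)

from conftest import mixed_regimes, random_tree


def enumeration_loglik(tree, regimes, q_lh, q_hl):
    """Oracle: sum over all internal-node state assignments, with transition
    probabilities from an independent matrix exponential."""
    states = regimes.state_vector(tree)
    tips = {t: k for k, t in enumerate(tree.tips)}
    internals = [i for i in range(tree.n_nodes) if tree.children(i)]
    Q = np.array([[-q_lh, q_lh], [q_hl, -q_hl]])
    P = {n: expm(Q * tree.lengths[n]) for n in range(1, tree.n_nodes)}
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internals)):
        st = dict(zip(internals, assign))
        for t in tree.tips:
            st[t] = states[tips[t]]
        p = 0.5
        for node in range(1, tree.n_nodes):
            p *= P[node][st[tree.parent[node]], st[node]]
        total += p
    return np.log(total) if total > 0 else -np.inf


class TestAssignRegimes:
    def test_gradient_endpoints(self):
        reg = ev.assign_regimes({"a": 400.0, "b": 2800.0}, ["a", "b"])
        assert reg.states["a"] == LOW and reg.states["b"] == HIGH

    def test_boundary_is_low(self):
        reg = ev.assign_regimes({"a": 1500.0}, ["a"], threshold_m=1500.0)
        assert reg.states["a"] == LOW

    def test_all_above_threshold(self):
        reg = ev.assign_regimes({"a": 1600.0, "b": 2000.0}, ["a", "b"])
        assert set(reg.states.values()) == {HIGH}

    def test_missing_species_listed(self):
        with pytest.raises(ValueError, match="b"):
            ev.assign_regimes({"a": 100.0}, ["a", "b"])


class TestMkLoglik:
    def test_zero_rates_uniform_tips(self, tree5):
        reg = ev.RegimeAssignment({s: LOW for s in tree5.tip_labels}, 1500.0)
        assert ev.mk_loglik(tree5, reg, 0.0, 0.0) == pytest.approx(np.log(0.5))

    def test_zero_rates_mixed_tips_impossible(self, tree5):
        states = {s: (LOW if i else HIGH) for i, s in enumerate(tree5.tip_labels)}
        reg = ev.RegimeAssignment(states, 1500.0)
        assert ev.mk_loglik(tree5, reg, 0.0, 0.0) == -np.inf

    def test_negative_rates_error(self, tree5):
        reg = ev.RegimeAssignment({s: LOW for s in tree5.tip_labels}, 1500.0)
        with pytest.raises(ValueError):
            ev.mk_loglik(tree5, reg, -0.1, 0.2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_tree(rng, int(rng.integers(3, 7)))
        smap, reg = mixed_regimes(tree, rng, 0.2, 0.3)
        q = rng.uniform(0.02, 1.0, 2)
        ll = ev.mk_loglik(tree, reg, q[0], q[1])
        assert ll == pytest.approx(enumeration_loglik(tree, reg, q[0], q[1]), abs=1e-10)

    def test_tip_order_invariance(self):
        a = ev.parse_newick("((A:1,B:1):1,C:2):0;")
        b = ev.parse_newick("(C:2,(B:1,A:1):1):0;")
        reg = ev.RegimeAssignment({"A": LOW, "B": HIGH, "C": LOW}, 1500.0)
        assert ev.mk_loglik(a, reg, 0.3, 0.6) == pytest.approx(
            ev.mk_loglik(b, reg, 0.3, 0.6), abs=1e-12
        )


class TestFitMk:
    def test_single_state_boundary(self, tree5):
        reg = ev.RegimeAssignment({s: LOW for s in tree5.tip_labels}, 1500.0)
        # ER: no changes possible at the rate floor; only the root prior counts
        fit = ev.fit_mk(tree5, reg, "ER")
        assert fit.q_low_high < 1e-4
        assert fit.loglik == pytest.approx(np.log(0.5), abs=1e-4)
        # ARD escapes via an instantaneous high->low flicker (flat root
        # prior), so only the low->high rate is pinned at the floor
        ard = ev.fit_mk(tree5, reg, "ARD")
        assert ard.q_low_high < 1e-4
        assert ard.loglik >= fit.loglik - 1e-8

    def test_er_preferred_on_symmetric_truth(self):
        rng = np.random.default_rng(7)
        wins = 0
        n = 7
        for _ in range(n):
            tree = random_tree(rng, 80, height=10.0)
            smap, reg = mixed_regimes(tree, rng, 0.15, 0.15)
            er = ev.fit_mk(tree, reg, "ER")
            ard = ev.fit_mk(tree, reg, "ARD")
            wins += er.aic < ard.aic
        assert wins > n / 2

    def test_asymmetric_rates_recovered(self):
        # generating values: asymmetric reference rates low->high 0.030, high->low 0.910
        rng = np.random.default_rng(8)
        rel_err = []
        for _ in range(8):
            tree = random_tree(rng, 150, height=30.0)
            smap, reg = mixed_regimes(tree, rng, 0.030, 0.910, max_tries=200)
            fit = ev.fit_mk(tree, reg, "ARD")
            rel_err.append(abs(fit.q_high_low - 0.910) / 0.910)
        assert np.median(rel_err) < 0.5

    def test_er_rates_equal(self, tree5):
        rng = np.random.default_rng(9)
        smap, reg = mixed_regimes(tree5, rng, 0.3, 0.3)
        fit = ev.fit_mk(tree5, reg, "ER")
        assert fit.q_low_high == fit.q_high_low
        assert fit.k == 1


class TestStochasticMaps:
    def test_zero_rates_single_state(self, tree5):
        reg = ev.RegimeAssignment({s: HIGH for s in tree5.tip_labels}, 1500.0)
        fit = ev.MkFit("ER", 0.0, 0.0, np.log(0.5), 1, 0.0)
        maps = ev.sample_stochastic_maps(tree5, reg, fit, 10, seed=1)
        for m in maps:
            assert m.root_state == HIGH
            for segs in m.segments.values():
                assert all(s == HIGH for _, s in segs)

    def test_zero_rates_mixed_tips_error(self, tree5):
        states = {s: (LOW if i else HIGH) for i, s in enumerate(tree5.tip_labels)}
        reg = ev.RegimeAssignment(states, 1500.0)
        fit = ev.MkFit("ER", 0.0, 0.0, -1.0, 1, 0.0)
        with pytest.raises(ValueError, match="history"):
            ev.sample_stochastic_maps(tree5, reg, fit, 1, seed=1)

    def test_map_invariants(self, tree5):
        rng = np.random.default_rng(10)
        smap, reg = mixed_regimes(tree5, rng, 0.15, 0.25)
        fit = ev.fit_mk(tree5, reg, "ARD")
        maps = ev.sample_stochastic_maps(tree5, reg, fit, 100, seed=2)
        assert len(maps) == 100
        states = reg.state_vector(tree5)
        for m in maps:
            for node in range(1, tree5.n_nodes):
                segs = m.segments[node]
                assert sum(d for d, _ in segs) == pytest.approx(
                    tree5.lengths[node], abs=1e-9
                )
                for (_, s1), (_, s2) in zip(segs, segs[1:]):
                    assert s1 != s2
            assert np.array_equal(m.tip_states(tree5), states)

    def test_conditioned_jump_count_matches_conditioned_simulation(self):
        # single branch, endpoints low->low, length 10, rates (0.1, 0.1):
        # our samplers vs. plain forward simulation kept when it ends low
        rng = np.random.default_rng(11)
        t, q = 10.0, 0.1

        def n_jumps(jumps):
            return len(jumps)

        ours = []
        for _ in range(4000):
            j = _sample_path_rejection(rng, LOW, LOW, t, q, q)
            if j is None:
                j = _sample_path_uniformization(rng, LOW, LOW, t, q, q)
            ours.append(n_jumps(j))
        unif = [
            n_jumps(_sample_path_uniformization(rng, LOW, LOW, t, q, q))
            for _ in range(4000)
        ]
        # oracle: condition independent forward draws on the endpoint
        cond = []
        while len(cond) < 4000:
            state, now, k = LOW, 0.0, 0
            while True:
                now += rng.exponential(1.0 / q)
                if now >= t:
                    break
                state, k = 1 - state, k + 1
            if state == LOW:
                cond.append(k)
        m_ours, m_unif, m_cond = np.mean(ours), np.mean(unif), np.mean(cond)
        se = np.std(cond) / np.sqrt(len(cond))
        assert abs(m_ours - m_cond) < 5 * se
        assert abs(m_unif - m_cond) < 5 * se

    def test_node_frequencies_match_marginals(self, tree5):
        rng = np.random.default_rng(12)
        smap, reg = mixed_regimes(tree5, rng, 0.15, 0.25)
        fit = ev.MkFit("ARD", 0.15, 0.25, ev.mk_loglik(tree5, reg, 0.15, 0.25), 2, 0.0)
        maps = ev.sample_stochastic_maps(tree5, reg, fit, 2000, seed=3)
        marg = ev.node_marginals(tree5, reg, 0.15, 0.25)
        freq = np.zeros((tree5.n_nodes, 2))
        for m in maps:
            freq[0, m.root_state] += 1
            for node in range(1, tree5.n_nodes):
                freq[node, m.segments[node][-1][1]] += 1
        freq /= len(maps)
        tv = np.abs(freq - marg).sum(axis=1) / 2
        assert tv.max() < 0.05


class TestCarryMap:
    def test_carried_map_consistent(self):
        rng = np.random.default_rng(13)
        tree = random_tree(rng, 15)
        smap, reg = mixed_regimes(tree, rng, 0.2, 0.2)
        keep = list(rng.choice(tree.tip_labels, size=8, replace=False))
        pr = ev.prune_with_sources(tree, keep)
        carried = ev.carry_map(pr, smap)
        for node in range(1, pr.tree.n_nodes):
            assert sum(d for d, _ in carried.segments[node]) == pytest.approx(
                pr.tree.lengths[node], abs=1e-9
            )
        old_states = {s: reg.states[s] for s in keep}
        new_states = dict(
            zip(pr.tree.tip_labels, carried.tip_states(pr.tree))
        )
        assert all(new_states[s] == old_states[s] for s in keep)
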