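"""Fit the five trait-evolution models and pick a consensus across maps.

Simulates a trait under the adaptive two-optimum model (OUM) with the
asymptotic-size optima 70.16 mm (low elevation) and 23.65 mm (high), fits
WN / BM1 / BMM / OU1 / OUM on several stochastic regime maps, and reports
the consensus best model with its AICc margin and phylogenetic half-life.
"""

import numpy as np

import elevolve as ev

tree = ev.simulate_tree(n_taxa=100, height=30.0, seed=21)
smap, regimes = ev.simulate_regime_history(tree, 0.05, 0.05, seed=22)

truth = ev.EvoParams("OUM", alpha=0.2, sigma2=4.0, theta_low=70.16, theta_high=23.65)
data = ev.simulate_traits("OUM", tree, smap, truth, se_profile=1.0, seed=23)

fit = ev.fit_mk(tree, regimes, "ARD")
maps = ev.sample_stochastic_maps(tree, regimes, fit, n_maps=5, seed=24)
per_map = [ev.fit_all_models(tree, m, data, map_id=i) for i, m in enumerate(maps)]
mc = ev.consensus_best(per_map)

print(f"consensus model: {mc.consensus} ({mc.support}), votes {mc.votes}")
print(f"median dAICc to runner-up: {mc.delta_aicc:.2f} (<= -2 means clear support)")
print(f"estimated optima: theta_low {mc.theta_low:.2f}, theta_high {mc.theta_high:.2f} mm")
print(f"  (generating values were 70.16 and 23.65)")
print(
    f"phylogenetic half-life ln(2)/alpha = {mc.halflife:.2f} mya "
    f"(truth {np.log(2) / 0.2:.2f}); small values mean fast adaptation"
)

mean, sd, sig, _ = ev.bootstrap_half_life(
    tree, data, smaps=maps, model_policy="OUM", n_boot=50, seed=25
)
star = "significant" if sig else "not significant"
print(f"bootstrap (drop 1/3 of species): t1/2 = {mean:.2f} +/- {sd:.2f} mya, {star}")
print("  (half-life bootstraps are heavy-tailed: a few weak-pull refits can")
print("   inflate the mean, the same pattern seen in real half-life tables)")
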