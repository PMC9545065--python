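"""Multivariate screening: VIF pruning, DAPC, and trade-off correlations.

Standardizes a species x trait matrix, removes collinear columns at
VIF > 10, finds the discriminant axis separating low- from high-elevation
species, selects traits above the third quartile of contributions, and
screens them for negative pairwise correlations (candidate trade-offs).
"""

import numpy as np
import pandas as pd

import elevolve as ev

rng = np.random.default_rng(51)
n = 80
names = [f"trait{i}" for i in range(12)]
X = pd.DataFrame(rng.standard_normal((n, 12)), columns=names,
                 index=[f"sp{i}" for i in range(n)])
grp = pd.Series(["low"] * 40 + ["high"] * 40, index=X.index)
X.loc[grp == "high", "trait0"] += 2.5   # divergent trait
X["trait1"] = -0.8 * X["trait0"] + 0.6 * rng.standard_normal(n)  # trade-off
X["trait2"] = X["trait0"] + rng.normal(0, 0.05, n)  # collinear duplicate

z = ev.standardize(X)
kept, dropped = ev.vif_prune(z, threshold=10.0)
print(f"VIF pruning dropped {dropped} (collinear with retained traits)")

tm = ev.TraitMatrix(kept, grp)
n_pcs = ev.xval_pc_retention(tm, grid=[2, 4, 6, 8], reps=100, seed=52)
res = ev.dapc(tm, n_pcs=n_pcs)
print(f"retained {n_pcs} PCs; assignment accuracy {res.accuracy:.1%}")
top = ev.select_discriminating(res)
print(f"traits above the 3rd contribution quartile: {top}")

r, p, _, stars = ev.pearson_matrix(kept[top] if len(top) >= 2 else kept)
print("pairwise Pearson r (stars: * <0.05, ** <0.01, *** <0.001):")
for a in r.columns:
    for b in r.columns:
        if a < b and np.isfinite(r.loc[a, b]):
            print(f"  {a} ~ {b}: r = {r.loc[a, b]:+.2f}{stars.loc[a, b]}")
print("negative starred pairs are candidate trade-offs")
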