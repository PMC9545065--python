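"""Phylogenetic linear mixed models for treatment x elevation effects.

Species-by-treatment-by-round trait values are modeled with fixed effects
for growth treatment (contrasts against a stated baseline, "Mild" by
default), mean-centered median elevation, and their interaction; random
intercepts for sowing round; and a phylogenetic species effect whose
covariance is proportional to the shared-time matrix C.  Responses are
analyzed on the identity, log, or logit scale (logit for proportion-valued
resistance scores, with boundary shrinkage y' = (y (n-1) + 0.5)/n).

Estimation is maximum likelihood: fixed effects are profiled by GLS inside a
bounded search over variance-component ratios, and 90% intervals come from a
parametric bootstrap.  The contribution of phylogeny is judged by AICc of
the model with versus without the phylogenetic random effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .phylo import Tree, phylo_covariance
from .selection import aicc

__all__ = [
    "LmmSpec",
    "LmmFit",
    "fit_phylo_lmm",
    "compare_phylogeny",
    "significance_tiers",
]


@dataclass(frozen=True)
class LmmSpec:
    response: str
    transform: str = "identity"  # identity | log | logit
    baseline: str = "Mild"  # "Frost" for tolerance traits
    include_treatment: bool = True
    include_elevation: bool = True
    include_interaction: bool = True
    include_round: bool = True
    include_phylogeny: bool = True
    n_boot: int = 500

    def __post_init__(self):
        if self.transform not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class LmmFit:
    coef: pd.DataFrame  # term, estimate, lower90, upper90
    var_phylo: float
    var_round: float
    var_resid: float
    loglik: float
    aicc: float
    n: int
    draws: np.ndarray = field(repr=False, default=None)  # bootstrap fixed-effect draws
    terms: tuple = ()


def _transform(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return y
    if transform == "log":
        bad = np.where(y <= 0)[0]
        if len(bad):
            raise ValueError(f"log transform needs positive values; offending rows: {bad.tolist()}")
        return np.log(y)
    bad = np.where((y < 0) | (y > 1))[0]
    if len(bad):
        raise ValueError(f"logit transform needs values in [0, 1]; offending rows: {bad.tolist()}")
    n = len(y)
    y = (y * (n - 1) + 0.5) / n  # shrink away from the 0/1 boundary
    return np.log(y / (1.0 - y))


def _design(df: pd.DataFrame, spec: LmmSpec):
    treatments = sorted(df["treatment"].unique())
    if spec.include_treatment and spec.baseline not in treatments:
        raise ValueError(f"baseline {spec.baseline!r} not present in data")
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    others = [t for t in treatments if t != spec.baseline]
    if spec.include_treatment:
        for t in others:
            cols.append((df["treatment"] == t).to_numpy(float))
            names.append(f"{t} vs {spec.baseline}")
    if spec.include_elevation:
        elev = df["elevation_m"].to_numpy(float)
        elev_c = elev - elev.mean()  # mean-centered before fitting
        cols.append(elev_c)
        names.append("elevation")
        if spec.include_interaction and spec.include_treatment:
            for t in others:
                cols.append(((df["treatment"] == t).to_numpy(float)) * elev_c)
                names.append(f"{t} x elevation")
    return np.column_stack(cols), tuple(names)


def _random_structures(df: pd.DataFrame, spec: LmmSpec, tree: Tree | None):
    mats = []
    labels = []
    if spec.include_round and "round" in df.columns and df["round"].nunique() > 1:
        Zr = pd.get_dummies(df["round"]).to_numpy(float)
        mats.append(Zr @ Zr.T)
        labels.append("round")
    if spec.include_phylogeny:
        if tree is None:
            raise ValueError("phylogenetic random effect requires a tree")
        cov = phylo_covariance(tree)
        order = {s: i for i, s in enumerate(cov.species)}
        missing = sorted(set(df["species"]) - set(cov.species))
        if missing:
            raise ValueError(f"species absent from the tree: {missing}")
        idx = df["species"].map(order).to_numpy()
        Cn = cov.matrix / np.mean(np.diag(cov.matrix))  # unit-diagonal-ish scale
        mats.append(Cn[np.ix_(idx, idx)])
        labels.append("phylo")
    return mats, labels


def _profiled_nll(log_gamma, y, X, mats):
    n = len(y)
    V0 = np.eye(n)
    for g, M in zip(np.exp(log_gamma), mats):
        V0 = V0 + g * M
    try:
        c, low = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError:
        return 1e12, None
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    r = y - X @ beta
    s2 = float(r @ cho_solve((c, low), r)) / n
    if s2 <= 0:
        return 1e12, None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    nll = 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return nll, (beta, s2, np.exp(log_gamma))


def _fit_ml(y, X, mats, x0=None):
    if not mats:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        n = len(y)
        s2 = float(r @ r) / n
        ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
        return beta, s2, np.array([]), ll
    starts = [np.log(np.full(len(mats), g)) for g in (0.01, 0.3, 3.0)]
    if x0 is not None:
        starts = [x0] + starts
    best = None
    for s in starts:
        res = minimize(
            lambda x: _profiled_nll(x, y, X, mats)[0],
            s,
            method="L-BFGS-B",
            bounds=[(np.log(1e-8), np.log(1e6))] * len(mats),
            options={"maxiter": 100},
        )
        if best is None or res.fun < best.fun:
            best = res
        if x0 is not None:
            break  # warm start: single descent is enough inside the bootstrap
    nll, payload = _profiled_nll(best.x, y, X, mats)
    if payload is None:
        raise RuntimeError("mixed-model fit failed")
    beta, s2, gammas = payload
    return beta, s2, gammas, -nll


def fit_phylo_lmm(
    data: pd.DataFrame,
    spec: LmmSpec,
    tree: Tree | None = None,
    seed: int = 0,
) -> LmmFit:
    """ML fit of the phylogenetic mixed model.

    ``data`` is long-format with columns ``species``, ``treatment``,
    ``round``, ``elevation_m`` and the response named by ``spec.response``.
    Returns coefficients with 90% parametric-bootstrap intervals, variance
    components, log-likelihood and AICc.
    """
    df = data.reset_index(drop=True)
    if df["species"].nunique() < 10:
        raise ValueError("need at least 10 species")
    y = _transform(df[spec.response].to_numpy(float), spec.transform)
    X, names = _design(df, spec)
    mats, labels = _random_structures(df, spec, tree)
    beta, s2, gammas, ll = _fit_ml(y, X, mats)
    n = len(y)
    k = X.shape[1] + 1 + len(mats)  # fixed effects + resid var + var comps
    var = dict(zip(labels, gammas * s2)) if len(gammas) else {}

    # parametric bootstrap of the fixed effects; the ML residual variance is
    # rescaled by n/(n-p) so simulated noise is not systematically too small
    rng = np.random.default_rng(seed)
    s2b = s2 * n / max(n - X.shape[1], 1)
    V = s2b * np.eye(n)
    for g, M in zip(gammas, mats):
        V = V + s2b * g * M
    L = np.linalg.cholesky(V + 1e-10 * np.trace(V) / n * np.eye(n))
    mu = X @ beta
    x0 = np.log(np.maximum(gammas, 1e-8)) if len(gammas) else None
    draws = []
    for _ in range(spec.n_boot):
        yb = mu + L @ rng.standard_normal(n)
        try:
            bb, *_ = _fit_ml(yb, X, mats, x0=x0)
        except RuntimeError:
            continue
        draws.append(bb)
    draws = np.array(draws) if draws else beta[None, :]
    lo = np.percentile(draws, 5, axis=0)
    hi = np.percentile(draws, 95, axis=0)
    coef = pd.DataFrame(
        {"term": names, "estimate": beta, "lower90": lo, "upper90": hi}
    )
    return LmmFit(
        coef=coef,
        var_phylo=float(var.get("phylo", 0.0)),
        var_round=float(var.get("round", 0.0)),
        var_resid=float(s2),
        loglik=float(ll),
        aicc=float(aicc(ll, k, n)),
        n=n,
        draws=draws,
        terms=names,
    )


def compare_phylogeny(data: pd.DataFrame, spec: LmmSpec, tree: Tree, seed: int = 0) -> float:
    """dAICc = AICc(with phylogenetic effect) - AICc(without).

    Negative values favor the phylogeny-inclusive model.  Bootstrap is
    skipped for speed (only AICc is needed).
    """
    from dataclasses import replace

    quick = replace(spec, n_boot=0)
    with_p = fit_phylo_lmm(data, replace(quick, include_phylogeny=True), tree, seed)
    without = fit_phylo_lmm(data, replace(quick, include_phylogeny=False), tree, seed)
    return float(with_p.aicc - without.aicc)


def significance_tiers(fit: LmmFit) -> dict:
    """Probability-of-direction tiers per coefficient from bootstrap draws.

    pd = max(fraction of draws > 0, fraction < 0); tiers: *** pd > 99.95%,
    ** pd > 99.5%, * pd > 97.5%, (.) pd > 95%, else ns.
    """
    out = {}
    for j, term in enumerate(fit.terms):
        d = fit.draws[:, j]
        p = max(np.mean(d > 0), np.mean(d < 0))
        if p > 0.9995:
            tier = "***"
        elif p > 0.995:
            tier = "**"
        elif p > 0.975:
            tier = "*"
        elif p > 0.95:
            tier = "(.)"
        else:
            tier = "ns"
        out[term] = tier
    return out
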