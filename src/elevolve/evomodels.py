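"""Five trait-evolution models with species-mean measurement error.

The candidate set spans the standard hypotheses about a continuous trait's
macroevolutionary history:

* **WN** — white noise: species values i.i.d. around a mean, no phylogenetic
  structure (k = 2: mu, sigma^2).
* **BM1** — Brownian motion, one diffusion rate (k = 2: x0, sigma^2).
* **BMM** — Brownian motion with regime-specific diffusion rates along a
  stochastic regime map (k = 3: x0, sigma^2_low, sigma^2_high).
* **OU1** — Ornstein-Uhlenbeck pull toward a single optimum theta
  (k = 3: alpha, sigma^2, theta).
* **OUM** — OU with regime-specific optima theta_low / theta_high, shared
  alpha and sigma^2 (k = 4).

Species means carry known measurement error: the standard error of the
species mean across sowing rounds enters the model covariance as a fixed
diagonal SE^2 term, never as a free parameter.  Location parameters (mu, x0,
theta) are profiled out by generalized least squares at each evaluation of
(alpha, sigma^2), which are searched on the log scale from a multi-start
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize

from .phylo import Tree, is_ultrametric, phylo_covariance
from .regimes import HIGH, LOW, StochasticMap

__all__ = [
    "MODELS",
    "TraitData",
    "EvoParams",
    "EvoFit",
    "model_mean",
    "model_covariance",
    "model_loglik",
    "fit_evo_model",
    "simulate_traits",
]

MODELS = ("WN", "BM1", "BMM", "OU1", "OUM")
K_PARAMS = {"WN": 2, "BM1": 2, "BMM": 3, "OU1": 3, "OUM": 4}

_ALPHA_LO, _ALPHA_HI = 1e-4, 1e2
_N_STARTS = 10


@dataclass(frozen=True)
class TraitData:
    """Species trait means with measurement error.

    ``se`` is the standard error of each species mean (across sowing
    rounds); species present in a single round get the trait's median SE
    imputed upstream and are flagged there.
    """

    species: tuple
    mean: np.ndarray
    se: np.ndarray
    n_rounds: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "se", np.asarray(self.se, dtype=float))
        if np.any(self.se < 0):
            raise ValueError("standard errors must be >= 0")
        if len(self.species) != len(self.mean) or len(self.mean) != len(self.se):
            raise ValueError("species/mean/se length mismatch")

    def aligned_to(self, tree: Tree) -> "TraitData":
        idx = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in tree.tip_labels if s not in idx]
        if missing:
            raise ValueError(f"no trait data for species: {missing}")
        order = [idx[s] for s in tree.tip_labels]
        nr = None if self.n_rounds is None else np.asarray(self.n_rounds)[order]
        return TraitData(tree.tip_labels, self.mean[order], self.se[order], nr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species, "mean": self.mean, "se": self.se}
        )


@dataclass(frozen=True)
class EvoParams:
    """Parameters of one of the five models; only the named model's fields
    are meaningful (others stay None)."""

    model: str
    mu: float | None = None  # WN mean
    x0: float | None = None  # BM root state
    sigma2: float | None = None  # diffusion variance per mya
    sigma2_low: float | None = None  # BMM regime rates
    sigma2_high: float | None = None
    alpha: float | None = None  # OU pull per mya
    theta: float | None = None  # OU1 optimum
    theta_low: float | None = None  # OUM optima
    theta_high: float | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model in ("OU1", "OUM") and self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0 for OU models")
        for f in ("sigma2", "sigma2_low", "sigma2_high"):
            v = getattr(self, f)
            if v is not None and v <= 0:
                raise ValueError(f"{f} must be > 0")


@dataclass(frozen=True)
class EvoFit:
    params: EvoParams
    loglik: float
    k: int
    aicc: float
    n_species: int
    converged: bool
    map_id: int | None = None


# -- shared per-(tree, map) structures --------------------------------------

class ModelContext:
    """Precomputed tree/map quantities reused across likelihood evaluations."""

    def __init__(self, tree: Tree, smap: StochasticMap | None, data: TraitData | None):
        self.tree = tree
        self.n = tree.n_tips
        self.C = phylo_covariance(tree).matrix
        self.T = float(np.max(np.diag(self.C)))
        self.ultrametric = is_ultrametric(tree, 1e-6)
        self.smap = smap
        if data is not None:
            data = data.aligned_to(tree)
            self.y = data.mean
            self.se2 = data.se**2
        else:
            self.y = None
            self.se2 = np.zeros(self.n)
        if smap is not None:
            self._prepare_map(smap)

    def _prepare_map(self, smap: StochasticMap):
        tree = self.tree
        # per-state accumulated shared time (for BMM): same recursion as C
        # but with per-edge state durations as "lengths"
        dur = np.zeros((tree.n_nodes, 2))
        stem_dur = np.zeros(2)
        for d, s in smap.stem_segments:
            stem_dur[s] += d
        for node in range(1, tree.n_nodes):
            for d, s in smap.segments[node]:
                dur[node, s] += d
        self.C_state = [
            _edge_value_covariance(tree, dur[:, s], stem_dur[s]) for s in (LOW, HIGH)
        ]
        # per-tip absolute-time segment lists (for the OUM mean): list of
        # (t_start, t_end, state) from the process origin to each tip
        depths = tree.depths()
        self.tip_segments = []
        for t in tree.tips:
            segs = []
            now = 0.0
            for d, s in smap.stem_segments:
                segs.append((now, now + d, s))
                now += d
            for node in tree.path_to_tip(t):
                for d, s in smap.segments[node]:
                    segs.append((now, now + d, s))
                    now += d
            if abs(now - depths[t]) > 1e-6 * max(self.T, 1.0):
                raise ValueError("map segment durations inconsistent with branch lengths")
            self.tip_segments.append(segs)
        self.origin_state = smap.origin_state
        # flat arrays for vectorized OUM design assembly
        rows, t0s, t1s, sts = [], [], [], []
        for i, segs in enumerate(self.tip_segments):
            for t0, t1, s in segs:
                rows.append(i)
                t0s.append(t0)
                t1s.append(t1)
                sts.append(s)
        self._seg_row = np.array(rows, dtype=int)
        self._seg_t0 = np.array(t0s)
        self._seg_t1 = np.array(t1s)
        self._seg_state = np.array(sts, dtype=int)

    # -- means -------------------------------------------------------------
    def oum_design(self, alpha: float) -> np.ndarray:
        """n x 2 matrix of optimum weights: E[x] = W @ (theta_low, theta_high).

        Weight of each root-to-tip regime segment [t0, t1] toward its state's
        optimum is exp(-a (T - t1)) - exp(-a (T - t0)); the root term
        x0 e^{-aT} goes to the origin state's column (x0 is pinned to the
        origin-regime optimum).  Rows sum to 1.
        """
        W = np.zeros((self.n, 2))
        T = self.T
        wseg = np.exp(-alpha * (T - self._seg_t1)) - np.exp(-alpha * (T - self._seg_t0))
        np.add.at(W, (self._seg_row, self._seg_state), wseg)
        W[:, self.origin_state] += np.exp(-alpha * T)
        return W

    # -- covariances (without SE) -------------------------------------------
    def cov(self, params: EvoParams) -> np.ndarray:
        m = params.model
        if m == "WN":
            return params.sigma2 * np.eye(self.n)
        if m == "BM1":
            return params.sigma2 * self.C
        if m == "BMM":
            return (
                params.sigma2_low * self.C_state[LOW]
                + params.sigma2_high * self.C_state[HIGH]
            )
        # OU1 / OUM: single alpha, single sigma2; needs contemporaneous tips
        if not self.ultrametric:
            raise ValueError("OU covariance requires an ultrametric tree")
        a, s2 = params.alpha, params.sigma2
        s_ij = self.C
        d_ij = 2.0 * (self.T - s_ij)
        return s2 / (2.0 * a) * np.exp(-a * d_ij) * (1.0 - np.exp(-2.0 * a * s_ij))

    def mean(self, params: EvoParams) -> np.ndarray:
        m = params.model
        if m == "WN":
            return np.full(self.n, params.mu)
        if m in ("BM1", "BMM"):
            return np.full(self.n, params.x0)
        if m == "OU1":
            return np.full(self.n, params.theta)
        if self.smap is None:
            raise ValueError("OUM requires a stochastic regime map")
        W = self.oum_design(params.alpha)
        return W @ np.array([params.theta_low, params.theta_high])


def _edge_value_covariance(tree: Tree, edge_values: np.ndarray, stem: float) -> np.ndarray:
    """MRCA-accumulation of arbitrary per-edge values (C with lengths
    replaced by ``edge_values``; ``stem`` plays the role of root_length)."""
    acc = np.empty(tree.n_nodes)
    acc[0] = stem
    for i in range(1, tree.n_nodes):
        acc[i] = acc[tree.parent[i]] + edge_values[i]
    tips = tree.tips
    pos = {t: k for k, t in enumerate(tips)}
    n = len(tips)
    M = np.zeros((n, n))
    tipsets = {}
    for node in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children(node)
        if not ch:
            tipsets[node] = [pos[node]]
            M[pos[node], pos[node]] = acc[node]
            continue
        sets = [tipsets.pop(c) for c in ch]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        M[i, j] = M[j, i] = acc[node]
        tipsets[node] = [i for s in sets for i in s]
    return M


# -- public operations ------------------------------------------------------

def model_mean(tree: Tree, smap: StochasticMap | None, params: EvoParams) -> np.ndarray:
    """Expected species values (in ``tree.tip_labels`` order)."""
    return ModelContext(tree, smap if params.model in ("BMM", "OUM") else None, None).mean(
        params
    )


def model_covariance(
    tree: Tree,
    smap: StochasticMap | None,
    params: EvoParams,
    data: TraitData | None = None,
) -> np.ndarray:
    """Model covariance among species means, plus diag(SE^2) if data given."""
    ctx = ModelContext(tree, smap if params.model in ("BMM", "OUM") else None, data)
    V = ctx.cov(params)
    return V + np.diag(ctx.se2)


def _mvn_loglik(y: np.ndarray, mu: np.ndarray, V: np.ndarray) -> float:
    """Multivariate-normal log-density via Cholesky (own implementation;
    cross-checked in tests against an independent dense evaluation)."""
    try:
        c, low = cho_factor(V, lower=True)
    except LinAlgError:
        w = np.linalg.eigvalsh(V)
        raise ValueError(f"singular model covariance (min eigenvalue {w[0]:.3e})")
    r = y - mu
    z = cho_solve((c, low), r)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    n = len(y)
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + r @ z))


def model_loglik(
    tree: Tree, smap: StochasticMap | None, params: EvoParams, data: TraitData
) -> float:
    """Log-likelihood of observed species means under the model."""
    ctx = ModelContext(tree, smap if params.model in ("BMM", "OUM") else None, data)
    V = ctx.cov(params) + np.diag(ctx.se2)
    return _mvn_loglik(ctx.y, ctx.mean(params), V)


# -- ML fitting -------------------------------------------------------------

def _gls_profile(y, X, V):
    """GLS estimate of location params and the resulting log-likelihood."""
    c, low = cho_factor(V, lower=True)
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    z = cho_solve((c, low), r)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    n = len(y)
    ll = -0.5 * (n * np.log(2.0 * np.pi) + logdet + r @ z)
    return beta, float(ll)


def _aicc(loglik: float, k: int, n: int) -> float:
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_evo_model(
    model: str,
    tree: Tree,
    smap: StochasticMap | None,
    data: TraitData,
    map_id: int | None = None,
) -> EvoFit:
    """Maximum-likelihood fit of one model, AICc included.

    Location parameters are profiled by GLS; alpha and sigma^2 are optimized
    on the log scale by bounded quasi-Newton from a 10-point multi-start
    grid of alpha in [1e-4, 1e2] per mya.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    k = K_PARAMS[model]
    ctx = ModelContext(tree, smap if model in ("BMM", "OUM") else None, data)
    n = ctx.n
    if n <= k + 1:
        raise ValueError(f"need more than k+1={k + 1} species, got {n}")
    y = ctx.y
    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0 and np.all(ctx.se2 == 0.0):
        raise ValueError("constant trait vector with zero SE: degenerate input")
    var_y = max(var_y, 1e-12)
    ones = np.ones((n, 1))

    def negloglik(x):
        try:
            if model == "WN":
                V = np.exp(x[0]) * np.eye(n)
                X = ones
            elif model == "BM1":
                V = np.exp(x[0]) * ctx.C
                X = ones
            elif model == "BMM":
                V = np.exp(x[0]) * ctx.C_state[LOW] + np.exp(x[1]) * ctx.C_state[HIGH]
                X = ones
            else:
                a, s2 = np.exp(x[0]), np.exp(x[1])
                p = EvoParams("OU1", alpha=a, sigma2=s2, theta=0.0)
                V = ctx.cov(p)
                X = ones if model == "OU1" else ctx.oum_design(a)
            V = V + np.diag(ctx.se2)
            _, ll = _gls_profile(y, X, V)
            return -ll
        except (ValueError, LinAlgError, np.linalg.LinAlgError):
            return 1e12

    T = max(ctx.T, 1e-12)
    if model in ("WN", "BM1", "BMM"):
        s2_grid = var_y / T * np.array([0.1, 1.0, 10.0]) if model != "WN" else var_y * np.array([0.3, 1.0, 3.0])
        starts = [np.log([s2] * (2 if model == "BMM" else 1)) for s2 in s2_grid]
        bounds = [(np.log(1e-12), np.log(1e12))] * (2 if model == "BMM" else 1)
    else:
        alphas = np.geomspace(_ALPHA_LO, _ALPHA_HI, _N_STARTS)
        starts = [np.log([a, max(var_y * 2 * a, 1e-12)]) for a in alphas]
        bounds = [
            (np.log(_ALPHA_LO), np.log(_ALPHA_HI)),
            (np.log(1e-12), np.log(1e12)),
        ]

    # score every start, then refine the most promising ones
    scored = sorted(starts, key=lambda x0: negloglik(np.asarray(x0)))
    n_refine = 3 if len(scored) > 3 else len(scored)
    best, diags = None, []
    for x0 in scored[:n_refine]:
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200})
        diags.append((list(np.exp(np.asarray(x0))), res.fun, res.message))
        if np.isfinite(res.fun) and res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"all optimizer starts failed for {model}: {diags}")

    x = best.x
    if model == "WN":
        V = np.exp(x[0]) * np.eye(n) + np.diag(ctx.se2)
        beta, ll = _gls_profile(y, ones, V)
        params = EvoParams("WN", mu=float(beta[0]), sigma2=float(np.exp(x[0])))
    elif model == "BM1":
        V = np.exp(x[0]) * ctx.C + np.diag(ctx.se2)
        beta, ll = _gls_profile(y, ones, V)
        params = EvoParams("BM1", x0=float(beta[0]), sigma2=float(np.exp(x[0])))
    elif model == "BMM":
        V = (
            np.exp(x[0]) * ctx.C_state[LOW]
            + np.exp(x[1]) * ctx.C_state[HIGH]
            + np.diag(ctx.se2)
        )
        beta, ll = _gls_profile(y, ones, V)
        params = EvoParams(
            "BMM",
            x0=float(beta[0]),
            sigma2_low=float(np.exp(x[0])),
            sigma2_high=float(np.exp(x[1])),
        )
    else:
        a, s2 = float(np.exp(x[0])), float(np.exp(x[1]))
        p = EvoParams("OU1", alpha=a, sigma2=s2, theta=0.0)
        V = ctx.cov(p) + np.diag(ctx.se2)
        if model == "OU1":
            beta, ll = _gls_profile(y, ones, V)
            params = EvoParams("OU1", alpha=a, sigma2=s2, theta=float(beta[0]))
        else:
            W = ctx.oum_design(a)
            beta, ll = _gls_profile(y, W, V)
            params = EvoParams(
                "OUM", alpha=a, sigma2=s2,
                theta_low=float(beta[0]), theta_high=float(beta[1]),
            )
    return EvoFit(
        params=params,
        loglik=float(ll),
        k=k,
        aicc=float(_aicc(ll, k, n)),
        n_species=n,
        converged=bool(best.success),
        map_id=map_id,
    )


def fit_all_models(tree: Tree, smap: StochasticMap, data: TraitData,
                   map_id: int | None = None) -> dict:
    """Fit the full five-model set on one map; failed fits are recorded as
    None (and excluded per map downstream)."""
    out = {}
    for m in MODELS:
        try:
            out[m] = fit_evo_model(m, tree, smap, data, map_id=map_id)
        except (ValueError, RuntimeError):
            out[m] = None
    return out


# -- simulation -------------------------------------------------------------

def simulate_traits(
    model: str,
    tree: Tree,
    smap: StochasticMap | None,
    params: EvoParams,
    se_profile,
    seed: int,
) -> TraitData:
    """One draw of species means: MVN(model mean, model covariance) plus
    independent measurement noise with SD = SE per species."""
    rng = np.random.default_rng(seed)
    ctx = ModelContext(tree, smap if model in ("BMM", "OUM") else None, None)
    mu = ctx.mean(params)
    V = ctx.cov(params)
    se = np.broadcast_to(np.asarray(se_profile, dtype=float), (ctx.n,)).copy()
    n = ctx.n
    # Cholesky with a tiny jitter to absorb exact ties in shared times
    jitter = 1e-12 * max(np.trace(V) / n, 1.0)
    L = np.linalg.cholesky(V + jitter * np.eye(n))
    x = mu + L @ rng.standard_normal(n)
    x = x + rng.standard_normal(n) * se
    return TraitData(tree.tip_labels, x, se)
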