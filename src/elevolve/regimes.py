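"""Binary elevational regimes: Mk switch models and stochastic character maps.

Species are classified "low" or "high" by their median elevation of
occurrence relative to a threshold (default 1500 m a.s.l., the foothill/
subalpine split).  Regime evolution along the tree is a 2-state
continuous-time Markov chain, either with one rate (ER) or separate
low->high and high->low rates (ARD), fitted by maximum likelihood with the
pruning algorithm and a flat root prior.  Stochastic character maps are full
regime histories on every branch sampled from the posterior given the tip
states; they feed the multi-regime trait models.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy.optimize import minimize

from .phylo import Tree

__all__ = [
    "LOW",
    "HIGH",
    "STATES",
    "RegimeAssignment",
    "MkFit",
    "StochasticMap",
    "assign_regimes",
    "mk_loglik",
    "fit_mk",
    "sample_stochastic_maps",
    "node_marginals",
]

LOW, HIGH = 0, 1
STATES = ("low", "high")

RATE_LO, RATE_HI = 1e-6, 100.0  # per-mya bounds for ML rate search


@dataclass(frozen=True)
class RegimeAssignment:
    """Species -> regime state, with the elevation threshold that made it."""

    states: dict  # species -> LOW | HIGH
    threshold_m: float

    def state_vector(self, tree: Tree) -> np.ndarray:
        missing = [s for s in tree.tip_labels if s not in self.states]
        if missing:
            raise ValueError(f"no regime for species: {missing}")
        return np.array([self.states[s] for s in tree.tip_labels], dtype=int)


@dataclass(frozen=True)
class MkFit:
    model: str  # "ER" | "ARD"
    q_low_high: float  # events per mya
    q_high_low: float
    loglik: float
    k: int
    aic: float


@dataclass(frozen=True)
class StochasticMap:
    """Per-edge piecewise regime history.

    ``segments[node]`` is an ordered list of ``(duration_mya, state)`` pairs
    for the edge above ``node``, from the parent end to the node end; their
    durations sum to the branch length and adjacent segments differ in state.
    ``root_state`` is the state at the root itself.
    """

    segments: dict
    root_state: int
    rates: tuple = (np.nan, np.nan)
    seed: int | None = None
    stem_segments: tuple = ()  # history along a stem (pruned-root) edge

    @property
    def origin_state(self) -> int:
        """State at the very start of the process (top of the stem, if any)."""
        if self.stem_segments:
            return self.stem_segments[0][1]
        return self.root_state

    def tip_states(self, tree: Tree) -> np.ndarray:
        out = []
        for t in tree.tips:
            segs = self.segments[t] if t != 0 else [(0.0, self.root_state)]
            out.append(segs[-1][1])
        return np.array(out, dtype=int)


def assign_regimes(elevations: dict, species, threshold_m: float = 1500.0) -> RegimeAssignment:
    """Classify species low/high by median elevation.

    A species exactly at the threshold is "low" (closed-low convention).
    ``species`` is the required species set (usually the tree's tip labels);
    missing elevations raise an error listing the offenders.
    """
    species = list(species)
    missing = sorted(s for s in species if s not in elevations)
    if missing:
        raise ValueError(f"missing elevation for species: {missing}")
    states = {s: (LOW if elevations[s] <= threshold_m else HIGH) for s in species}
    return RegimeAssignment(states, threshold_m)


# -- 2-state transition probabilities (closed form) -------------------------

def _pmatrix(q_lh: float, q_hl: float, t: float) -> np.ndarray:
    s = q_lh + q_hl
    if s == 0.0 or t == 0.0:
        return np.eye(2)
    e = np.exp(-s * t)
    pi_l, pi_h = q_hl / s, q_lh / s
    return np.array(
        [
            [pi_l + pi_h * e, pi_h - pi_h * e],
            [pi_l - pi_l * e, pi_h + pi_l * e],
        ]
    )


def _tip_partials(tree: Tree, states: np.ndarray) -> np.ndarray:
    """Conditional likelihood array, tips initialized, internals zeroed."""
    L = np.zeros((tree.n_nodes, 2))
    for k, t in enumerate(tree.tips):
        L[t, states[k]] = 1.0
    return L


def _pruning(tree: Tree, states: np.ndarray, q_lh: float, q_hl: float):
    """Postorder partial likelihoods with per-node log scaling.

    Returns (L, logscale, P) where P[node] is the transition matrix along the
    edge above ``node``.
    """
    L = _tip_partials(tree, states)
    logscale = 0.0
    P = [None] * tree.n_nodes
    for node in range(1, tree.n_nodes):
        P[node] = _pmatrix(q_lh, q_hl, tree.lengths[node])
    for node in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children(node)
        if not ch:
            continue
        part = np.ones(2)
        for c in ch:
            part = part * (P[c] @ L[c])
        m = part.max()
        if m <= 0.0:
            return L, -np.inf, P
        L[node] = part / m
        logscale += np.log(m)
    return L, logscale, P


def mk_loglik(tree: Tree, regimes: RegimeAssignment, q_lh: float, q_hl: float) -> float:
    """Log-likelihood of tip regimes under the 2-state Markov model.

    Pruning recursion with closed-form 2x2 transition matrices and a flat
    (1/2, 1/2) root prior.
    """
    if q_lh < 0 or q_hl < 0:
        raise ValueError("rates must be non-negative")
    states = regimes.state_vector(tree)
    L, logscale, _ = _pruning(tree, states, q_lh, q_hl)
    if not np.isfinite(logscale):
        return -np.inf
    root = 0.5 * L[0].sum()
    if root <= 0.0:
        return -np.inf
    return float(np.log(root) + logscale)


def fit_mk(tree: Tree, regimes: RegimeAssignment, model: str = "ARD") -> MkFit:
    """ML fit of the ER or ARD switch model.

    Bounded quasi-Newton on log rates from an 8-point multi-start grid over
    [1e-6, 100] per mya; AIC = -2 logL + 2k with k = 1 (ER) or 2 (ARD).
    """
    if model not in ("ER", "ARD"):
        raise ValueError("model must be 'ER' or 'ARD'")
    states = regimes.state_vector(tree)
    ndim = 1 if model == "ER" else 2

    def nll(logq):
        q = np.exp(logq)
        q_lh, q_hl = (q[0], q[0]) if model == "ER" else (q[0], q[1])
        ll = mk_loglik(tree, regimes, q_lh, q_hl)
        return -ll if np.isfinite(ll) else 1e12

    starts = np.log(np.geomspace(1e-3, 10.0, 8))
    best = None
    diagnostics = []
    for s in starts:
        x0 = np.full(ndim, s)
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(np.log(RATE_LO), np.log(RATE_HI))] * ndim,
        )
        diagnostics.append((s, res.fun, res.message))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= 1e12:
        raise RuntimeError(f"Mk fit failed to converge; per-start results: {diagnostics}")
    q = np.exp(best.x)
    q_lh, q_hl = (q[0], q[0]) if model == "ER" else (q[0], q[1])
    ll = -best.fun
    k = 1 if model == "ER" else 2
    return MkFit(model, float(q_lh), float(q_hl), float(ll), k, float(-2 * ll + 2 * k))


def node_marginals(tree: Tree, regimes: RegimeAssignment, q_lh: float, q_hl: float) -> np.ndarray:
    """Marginal posterior state probabilities at every node (flat root prior)."""
    states = regimes.state_vector(tree)
    L, logscale, P = _pruning(tree, states, q_lh, q_hl)
    if not np.isfinite(logscale):
        raise ValueError("tip data impossible under the given rates")
    up = np.zeros((tree.n_nodes, 2))  # prior-weighted "above" message
    up[0] = 0.5
    post = np.zeros((tree.n_nodes, 2))
    for node in range(tree.n_nodes):
        if node != 0:
            par = tree.parent[node]
            sib = np.ones(2)
            for c in tree.children(par):
                if c != node:
                    sib = sib * (P[c] @ L[c])
            msg = (up[par] * sib) @ P[node]
            up[node] = msg / msg.sum() if msg.sum() > 0 else msg
        w = up[node] * L[node]
        post[node] = w / w.sum()
    return post


def _merge_segments(segs) -> list:
    out = []
    for d, s in segs:
        if d <= 0.0 and out:
            continue
        if out and out[-1][1] == s:
            out[-1] = (out[-1][0] + d, s)
        else:
            out.append((d, s))
    return out


def carry_map(prune_result, smap: StochasticMap) -> StochasticMap:
    """Transfer a stochastic map onto a pruned tree.

    Each retained edge of the pruned tree concatenates the histories of the
    original edges it was merged from; edges absorbed into the stem become
    ``stem_segments``.  Requires the :class:`~elevolve.phylo.PruneResult`
    from ``prune_with_sources`` on the same original tree.
    """
    stem = list(smap.stem_segments)
    for old_edge in prune_result.stem_sources:
        stem.extend(smap.segments[old_edge])
    stem = _merge_segments(stem)
    segments = {}
    for new_node, sources in prune_result.edge_sources.items():
        segs = []
        for old_edge in sources:
            segs.extend(smap.segments[old_edge])
        segments[new_node] = _merge_segments(segs)
    root_state = stem[-1][1] if stem else smap.root_state
    return StochasticMap(
        segments, int(root_state), smap.rates, smap.seed, tuple(stem)
    )


# -- stochastic maps --------------------------------------------------------

def _sample_path_rejection(rng, a: int, b: int, t: float, q_lh: float, q_hl: float,
                           max_tries: int = 1000):
    """Forward-simulate the chain from state a for time t; accept if it ends
    in b.  Returns the jump times/states, or None after ``max_tries``."""
    rates = (q_lh, q_hl)
    for _ in range(max_tries):
        state, now = a, 0.0
        jumps = []
        while True:
            r = rates[state]
            if r <= 0.0:
                break
            now += rng.exponential(1.0 / r)
            if now >= t:
                break
            state = 1 - state
            jumps.append((now, state))
        if state == b:
            return jumps
    return None


def _sample_path_uniformization(rng, a: int, b: int, t: float, q_lh: float, q_hl: float):
    """Exact endpoint-conditioned path via uniformization (2-state chain)."""
    omega = max(q_lh, q_hl)
    if omega <= 0.0:
        return []
    R = np.eye(2) + np.array([[-q_lh, q_lh], [q_hl, -q_hl]]) / omega
    # P(N = n | a -> b in t) ∝ Pois(n; omega t) * (R^n)[a, b]
    pois_mean = omega * t
    nmax = int(pois_mean + 12 * np.sqrt(pois_mean) + 30)
    Rpow = [np.eye(2)]
    for _ in range(nmax):
        Rpow.append(Rpow[-1] @ R)
    logw = np.array(
        [
            n * np.log(pois_mean) - pois_mean - lgamma(n + 1)
            + (np.log(Rpow[n][a, b]) if Rpow[n][a, b] > 0 else -np.inf)
            for n in range(nmax + 1)
        ]
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    n = int(rng.choice(nmax + 1, p=w))
    if n == 0:
        return []
    times = np.sort(rng.uniform(0.0, t, size=n))
    # DTMC bridge over the uniformized chain
    states = []
    cur = a
    for k in range(1, n + 1):
        probs = np.array([R[cur, s] * Rpow[n - k][s, b] for s in (0, 1)])
        tot = probs.sum()
        cur = int(rng.choice(2, p=probs / tot)) if tot > 0 else cur
        states.append(cur)
    # keep only real (state-changing) jumps
    jumps = []
    prev = a
    for tk, sk in zip(times, states):
        if sk != prev:
            jumps.append((float(tk), int(sk)))
            prev = sk
    return jumps


def _jumps_to_segments(a: int, t: float, jumps) -> list:
    segs = []
    prev_t, prev_s = 0.0, a
    for tk, sk in jumps:
        segs.append((tk - prev_t, prev_s))
        prev_t, prev_s = tk, sk
    segs.append((t - prev_t, prev_s))
    return [(d, s) for d, s in segs if d > 0.0] or [(t, a)]


def sample_stochastic_maps(
    tree: Tree,
    regimes: RegimeAssignment,
    fit: MkFit,
    n_maps: int,
    seed: int,
) -> list:
    """Draw ``n_maps`` regime histories consistent with the tip states.

    Node states are sampled root-to-tip from their conditional distribution
    given the tips (pruning posteriors); within-branch histories conditional
    on endpoint states use rejection sampling with an exact uniformization
    fallback after 1000 rejected attempts.
    """
    if not np.isfinite(fit.loglik):
        raise ValueError("Mk fit has non-finite log-likelihood")
    q_lh, q_hl = fit.q_low_high, fit.q_high_low
    states = regimes.state_vector(tree)
    if q_lh == 0.0 and q_hl == 0.0 and len(set(states)) > 1:
        raise ValueError("both rates zero but tips are in mixed states: no valid history")
    L, logscale, P = _pruning(tree, states, q_lh, q_hl)
    if not np.isfinite(logscale):
        raise ValueError("tip data impossible under the fitted rates")
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=int)
        w = 0.5 * L[0]
        node_state[0] = rng.choice(2, p=w / w.sum())
        for node in range(1, tree.n_nodes):
            a = node_state[tree.parent[node]]
            w = P[node][a] * L[node]
            node_state[node] = rng.choice(2, p=w / w.sum())
        segments = {}
        for node in range(1, tree.n_nodes):
            a, b = node_state[tree.parent[node]], node_state[node]
            t = tree.lengths[node]
            if t == 0.0:
                segments[node] = [(0.0, b)]
                continue
            jumps = _sample_path_rejection(rng, a, b, t, q_lh, q_hl)
            if jumps is None:
                jumps = _sample_path_uniformization(rng, a, b, t, q_lh, q_hl)
            segments[node] = _jumps_to_segments(a, t, jumps)
        maps.append(
            StochasticMap(segments, int(node_state[0]), (q_lh, q_hl), seed)
        )
    return maps
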