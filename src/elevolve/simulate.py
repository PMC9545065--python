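"""Synthetic trees, regime histories, traits, and the full growth experiment.

This module makes every stage of the pipeline runnable and testable without
any external data: a pure-birth (Yule) tree stands in for the real
phylogeny, binary elevational regimes evolve forward under an asymmetric
2-state Markov process (default rates 0.030 low->high and 0.910 high->low
per mya, giving a stationary low-state fraction of ~0.97), species trait
means are drawn under any of the five evolutionary models with tip
measurement error, and the full experimental design — 100 taxa x 6 maternal
lines x 3 temperature treatments = 1800 individuals, measured as logistic
leaf-growth series plus proportion-valued resistance assays — is emulated
with regime-dependent asymptotic-size optima.

It also drives the validation study: false-positive / false-negative rates
of the adaptive (OUM) model over a grid of measurement-error levels and
optimum separations, and consensus stability under random removal of a
third of the species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evomodels import EvoParams, TraitData, fit_all_models, simulate_traits
from .growth import logistic
from .phylo import Tree, prune_with_sources
from .regimes import HIGH, LOW, RegimeAssignment, StochasticMap, carry_map
from .selection import consensus_best

__all__ = [
    "SyntheticConfig",
    "ExperimentData",
    "ValidationReport",
    "simulate_tree",
    "simulate_regime_history",
    "simulate_experiment",
    "run_validation_study",
    "run_bootstrap_robustness",
]

# Regime-dependent asymptotic-size optima (mm), low/high, per growth
# treatment; realistic magnitudes for rosette leaf lengths.
DEFAULT_ASYM_OPTIMA = {
    "Frost": (57.15, 30.44),
    "Mild": (64.85, 38.72),
    "Heat": (70.16, 23.65),
}
DEFAULT_XMID_DAYS = {"Frost": 14.0, "Mild": 16.0, "Heat": 12.0}
DEFAULT_SCAL_DAYS = {"Frost": 3.5, "Mild": 4.0, "Heat": 3.0}
# resistance assay means on the probability scale, low/high
DEFAULT_RESISTANCE_MEANS = {"Frost": (0.55, 0.60), "Mild": (0.65, 0.55), "Heat": (0.70, 0.50)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the study design: 100 taxa, two populations of three
    maternal lines each (six lines, one per block), three temperature
    treatments, two sowing rounds, and reference switch rates and
    asymptotic-size optima as generating values.
    """

    n_taxa: int = 100
    tree_height: float = 30.0  # mya
    q_low_high: float = 0.030  # per mya
    q_high_low: float = 0.910
    n_populations: int = 2
    n_lines_per_population: int = 3
    treatments: tuple = ("Frost", "Mild", "Heat")
    n_rounds: int = 2
    time_grid: tuple = (3, 7, 10, 14, 17, 21, 24, 28, 31, 35)  # days
    alpha: float = 0.2  # OU pull for species-level ASYM evolution, per mya
    sigma2: float = 4.0  # OU diffusion variance, mm^2 per mya
    asym_optima: dict = field(default_factory=lambda: dict(DEFAULT_ASYM_OPTIMA))
    xmid_days: dict = field(default_factory=lambda: dict(DEFAULT_XMID_DAYS))
    scal_days: dict = field(default_factory=lambda: dict(DEFAULT_SCAL_DAYS))
    resistance_means: dict = field(default_factory=lambda: dict(DEFAULT_RESISTANCE_MEANS))
    sd_species_xmid: float = 1.5  # days, species effect on timing
    sd_line: float = 2.0  # mm, maternal-line effect on ASYM
    sd_block: float = 0.0  # mm, block effect (off by default)
    sd_resid: float = 0.5  # mm, per-observation measurement noise
    sd_resistance_logit: float = 0.5
    elevation_range_m: tuple = (400.0, 2800.0)
    threshold_m: float = 1500.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_taxa", "n_populations", "n_lines_per_population", "n_rounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def simulate_tree(n_taxa: int, height: float = 30.0, seed: int = 0) -> Tree:
    """Pure-birth (Yule) tree rescaled to the requested height (ultrametric)."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    # events: with k lineages, next split after Exp(k); a random lineage splits
    parent_of = {0: -1}
    birth = {0: 0.0}
    active = [1, 2]
    parent_of[1] = parent_of[2] = 0
    now = 0.0
    next_id = 3
    times = {0: 0.0}
    while len(active) < n_taxa:
        now += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        times[node] = now
        a, b = next_id, next_id + 1
        next_id += 2
        parent_of[a] = parent_of[b] = node
        active.extend([a, b])
    now += rng.exponential(1.0 / len(active))  # present = one more waiting time
    for tip in active:
        times[tip] = now
    scale = height / now
    # assemble preorder arrays
    children: dict = {}
    for c, p in parent_of.items():
        if p != -1:
            children.setdefault(p, []).append(c)
    parent_out, lengths_out, labels_out = [-1], [0.0], [None]
    tip_counter = [0]
    index = {0: 0}

    def build(old, new_parent):
        for c in children.get(old, []):
            idx = len(parent_out)
            index[c] = idx
            parent_out.append(new_parent)
            lengths_out.append((times[c] - times[old]) * scale)
            if c in children:
                labels_out.append(None)
            else:
                tip_counter[0] += 1
                labels_out.append(f"t{tip_counter[0]}")
            build(c, idx)

    build(0, 0)
    return Tree(np.array(parent_out), np.array(lengths_out), tuple(labels_out))


def simulate_regime_history(tree: Tree, q_lh: float, q_hl: float, seed: int = 0):
    """Forward 2-state Markov simulation of elevational regimes.

    The root state is drawn from the stationary distribution of the rates
    (flat when both rates are zero, in which case the history is constant).
    Returns the true :class:`StochasticMap` and the tip
    :class:`RegimeAssignment` it implies.
    """
    if q_lh < 0 or q_hl < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    s = q_lh + q_hl
    p_low = q_hl / s if s > 0 else 0.5
    root_state = LOW if rng.random() < p_low else HIGH
    rates = (q_lh, q_hl)
    node_state = {0: root_state}
    segments = {}
    for node in range(1, tree.n_nodes):
        state = node_state[tree.parent[node]]
        t = tree.lengths[node]
        segs, now = [], 0.0
        while True:
            r = rates[state]
            if r <= 0:
                break
            w = rng.exponential(1.0 / r)
            if now + w >= t:
                break
            segs.append((w, state))
            state = 1 - state
            now += w
        segs.append((t - now, state))
        segments[node] = segs
        node_state[node] = state
    smap = StochasticMap(segments, root_state, rates, seed)
    states = {tree.labels[t]: node_state[t] for t in tree.tips}
    return smap, RegimeAssignment(states, threshold_m=float("nan"))


def _simulate_elevations(regimes: RegimeAssignment, cfg: SyntheticConfig, rng) -> dict:
    lo, hi = cfg.elevation_range_m
    out = {}
    for sp, st in regimes.states.items():
        if st == LOW:
            out[sp] = float(rng.uniform(lo, cfg.threshold_m))
        else:
            out[sp] = float(rng.uniform(np.nextafter(cfg.threshold_m, np.inf), hi))
    return out


@dataclass
class ExperimentData:
    """Synthetic experiment: tree, regimes, per-plant records, and truth."""

    tree: Tree
    smap: StochasticMap
    regimes: RegimeAssignment
    elevations: dict
    plants: pd.DataFrame  # one row per individual, with resistance value
    growth: pd.DataFrame  # long format: plant x day leaf lengths
    species_truth: pd.DataFrame  # species x treatment generating parameters
    config: SyntheticConfig


def simulate_experiment(cfg: SyntheticConfig = SyntheticConfig()) -> ExperimentData:
    """Emulate the full raising experiment.

    Species-level asymptotic size evolves under OUM toward regime-dependent
    optima per treatment; XMID carries a species effect shared across
    treatments; maternal-line, block and residual noise act below the
    species level.  Growth series follow the three-parameter logistic on the
    configured day grid; resistance assays are logit-normal draws around
    regime-dependent means.  One plant is produced per taxon x line x
    treatment, so defaults yield 100 x 6 x 3 = 1800 individuals.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_taxa, cfg.tree_height, int(rng.integers(2**31)))
    smap, regimes = simulate_regime_history(
        tree, cfg.q_low_high, cfg.q_high_low, int(rng.integers(2**31))
    )
    elevations = _simulate_elevations(regimes, cfg, rng)
    species = tree.tip_labels
    state = np.array([regimes.states[s] for s in species])

    # species-level ASYM per treatment: one OUM draw on the true history
    asym_sp = {}
    for tr in cfg.treatments:
        th_lo, th_hi = cfg.asym_optima[tr]
        params = EvoParams(
            "OUM", alpha=cfg.alpha, sigma2=cfg.sigma2, theta_low=th_lo, theta_high=th_hi
        )
        td = simulate_traits("OUM", tree, smap, params, 0.0, int(rng.integers(2**31)))
        asym_sp[tr] = np.maximum(td.mean, 5.0)  # keep sizes biologically positive

    xmid_species = rng.normal(0.0, cfg.sd_species_xmid, size=len(species))
    block_eff = rng.normal(0.0, cfg.sd_block, size=6 * 10)  # ample blocks

    truth_rows = []
    plant_rows = []
    growth_rows = []
    days = np.asarray(cfg.time_grid, dtype=float)
    n_lines = cfg.n_populations * cfg.n_lines_per_population
    plant_id = 0
    for i, sp in enumerate(species):
        for tr in cfg.treatments:
            truth_rows.append(
                {
                    "species": sp,
                    "treatment": tr,
                    "asym": asym_sp[tr][i],
                    "xmid": cfg.xmid_days[tr] + xmid_species[i],
                    "scal": cfg.scal_days[tr],
                    "state": "low" if state[i] == LOW else "high",
                }
            )
        line_eff = rng.normal(0.0, cfg.sd_line, size=n_lines)
        for li in range(n_lines):
            pop = li // cfg.n_lines_per_population + 1
            block = li + 1  # one maternal line per block
            rnd = "S1" if li < n_lines / 2 else "S2"
            for tr in cfg.treatments:
                plant_id += 1
                pid = f"p{plant_id:05d}"
                asym = max(asym_sp[tr][i] + line_eff[li] + block_eff[block - 1], 1.0)
                xmid = cfg.xmid_days[tr] + xmid_species[i] + rng.normal(0, 0.3)
                scal = max(cfg.scal_days[tr] * np.exp(rng.normal(0, 0.05)), 0.5)
                y = logistic(days, asym, xmid, scal) + rng.normal(
                    0, cfg.sd_resid, size=len(days)
                )
                y = np.maximum(y, 0.0)
                mu_lo, mu_hi = cfg.resistance_means[tr]
                mu = mu_lo if state[i] == LOW else mu_hi
                z = np.log(mu / (1 - mu)) + rng.normal(0, cfg.sd_resistance_logit)
                resistance = 1.0 / (1.0 + np.exp(-z))
                plant_rows.append(
                    {
                        "plant": pid,
                        "species": sp,
                        "population": f"{sp}_P{pop}",
                        "line": f"{sp}_L{li + 1}",
                        "block": block,
                        "treatment": tr,
                        "round": rnd,
                        "resistance": resistance,
                        "elevation_m": elevations[sp],
                    }
                )
                for d, yy in zip(days, y):
                    growth_rows.append(
                        {
                            "plant": pid,
                            "species": sp,
                            "population": f"{sp}_P{pop}",
                            "line": f"{sp}_L{li + 1}",
                            "block": block,
                            "treatment": tr,
                            "round": rnd,
                            "day": d,
                            "leaf_length_mm": yy,
                        }
                    )
    return ExperimentData(
        tree=tree,
        smap=smap,
        regimes=regimes,
        elevations=elevations,
        plants=pd.DataFrame(plant_rows),
        growth=pd.DataFrame(growth_rows),
        species_truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


@dataclass
class ValidationReport:
    """Consensus counts and OUM error rates over a simulation grid."""

    table: pd.DataFrame  # per cell: generating model, se, delta_theta, counts
    fp_rate: float  # OUM chosen when truth is not OUM
    fn_rate: float  # OUM missed when truth is OUM


def run_validation_study(
    tree: Tree,
    smap: StochasticMap,
    se_levels=(0.0, 1.0),
    delta_levels=(0.0, 20.0),
    gen_models=("BM1", "OUM"),
    replicates: int = 20,
    seed: int = 0,
    alpha: float = 0.2,
    sigma2: float = 4.0,
) -> ValidationReport:
    """Power / false-positive study for the adaptive (OUM) model.

    Per grid cell (generating model x SE level x optimum separation),
    ``replicates`` datasets are simulated on the tree's true regime history,
    all five models are fitted on that history, and the per-replicate winner
    recorded.  OUM false positives are wins when the truth was not OUM;
    false negatives are misses when it was.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    fp_num = fp_den = fn_num = fn_den = 0
    for gm in gen_models:
        deltas = delta_levels if gm == "OUM" else (0.0,)
        for dth in deltas:
            for se in se_levels:
                counts: dict = {}
                for _ in range(replicates):
                    sub = int(rng.integers(2**31))
                    if gm == "OUM":
                        params = EvoParams(
                            "OUM",
                            alpha=alpha,
                            sigma2=sigma2,
                            theta_low=0.0,
                            theta_high=dth,
                        )
                    elif gm == "BM1":
                        params = EvoParams("BM1", x0=0.0, sigma2=sigma2)
                    elif gm == "OU1":
                        params = EvoParams("OU1", alpha=alpha, sigma2=sigma2, theta=0.0)
                    else:
                        params = EvoParams("WN", mu=0.0, sigma2=sigma2)
                    data = simulate_traits(gm, tree, smap, params, se, sub)
                    fits = fit_all_models(tree, smap, data)
                    winner = consensus_best([fits]).consensus
                    counts[winner] = counts.get(winner, 0) + 1
                oum_wins = counts.get("OUM", 0)
                if gm == "OUM" and dth > 0:
                    fn_den += replicates
                    fn_num += replicates - oum_wins
                if gm != "OUM":
                    fp_den += replicates
                    fp_num += oum_wins
                rows.append(
                    {
                        "gen_model": gm,
                        "se": se,
                        "delta_theta": dth,
                        "replicates": replicates,
                        **{f"won_{m}": counts.get(m, 0) for m in ("WN", "BM1", "BMM", "OU1", "OUM")},
                    }
                )
    return ValidationReport(
        table=pd.DataFrame(rows),
        fp_rate=fp_num / fp_den if fp_den else float("nan"),
        fn_rate=fn_num / fn_den if fn_den else float("nan"),
    )


def run_bootstrap_robustness(
    tree: Tree,
    smaps,
    data: TraitData,
    remove_fraction: float = 1.0 / 3.0,
    replicates: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Consensus stability under random removal of a species fraction.

    The five-model consensus is computed once on the full data across the
    provided maps, then recomputed per replicate on a random subset with
    ``remove_fraction`` of species removed (maps carried through the prune).
    Returns a table with per-replicate consensus and agreement flag.
    """
    full = consensus_best(
        [fit_all_models(tree, m, data) for m in smaps]
    ).consensus
    rng = np.random.default_rng(seed)
    labels = list(tree.tip_labels)
    n = len(labels)
    n_drop = int(np.floor(n * remove_fraction))
    rows = []
    for rep in range(replicates):
        keep = labels
        if n_drop > 0:
            drop = set(rng.choice(n, size=n_drop, replace=False))
            keep = [lab for i, lab in enumerate(labels) if i not in drop]
        pr = prune_with_sources(tree, keep)
        idx = {s: i for i, s in enumerate(data.species)}
        order = [idx[s] for s in keep]
        sub = TraitData(tuple(keep), data.mean[order], data.se[order])
        per_map = [fit_all_models(pr.tree, carry_map(pr, m), sub) for m in smaps]
        cons = consensus_best(per_map).consensus
        rows.append({"replicate": rep, "consensus": cons, "agrees": cons == full})
    out = pd.DataFrame(rows)
    out.attrs["full_consensus"] = full
    return out
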