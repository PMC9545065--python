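"""AICc model comparison, consensus across regime maps, phylogenetic
half-life, and its bootstrap significance.

Because ancestral regimes are uncertain, the five-model comparison is run on
each of many stochastic character maps and summarized by consensus: the
modal per-map winner, with models within |dAICc| <= 2 of each other treated
as statistically equivalent ("among the best").  Phylogenetic half-life
t1/2 = ln(2)/alpha converts the OU pull strength into the time (mya) needed
to close half the distance to the optimum; its significance is assessed by
refitting after randomly removing a third of the species and requiring
mean - 1.64*SD > 0 across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evomodels
from .phylo import Tree, prune_with_sources
from .regimes import carry_map

__all__ = [
    "ModelComparison",
    "aicc",
    "consensus_best",
    "half_life",
    "bootstrap_half_life",
    "halflife_significant",
    "treatment_halflife_contrast",
]

EQUIVALENCE_DELTA = 2.0  # |dAICc| <= 2 counts as "among the best"


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelComparison:
    """Consensus across per-map five-model fits."""

    consensus: str
    support: str  # "clear" | "among-best"
    delta_aicc: float  # median over maps of (winner AICc - runner-up AICc)
    votes: dict  # model -> number of maps in which it won
    theta_low: float | None  # medians across maps of OUM optima
    theta_high: float | None
    alpha: float | None  # median alpha of the consensus model, if OU
    halflife: float | None
    mean_aicc: dict = field(default_factory=dict)  # model -> mean AICc over maps
    trait: str | None = None
    treatment: str | None = None


def _winner(fits: dict):
    """Min-AICc model in one map; AICc ties break toward fewer parameters."""
    ok = {m: f for m, f in fits.items() if f is not None}
    if not ok:
        return None, None
    order = sorted(ok, key=lambda m: (ok[m].aicc, ok[m].k))
    win = order[0]
    runner = order[1] if len(order) > 1 else None
    return win, runner


def consensus_best(per_map_fits, trait=None, treatment=None) -> ModelComparison:
    """Summarize five-model fits across stochastic maps.

    ``per_map_fits`` is a sequence (one entry per map) of dicts
    model-name -> :class:`~elevolve.evomodels.EvoFit` (or None for a failed
    fit, which is excluded for that map).  The consensus label is the modal
    per-map winner; the reported dAICc is the median across maps of
    (winner AICc - runner-up AICc), and support is "among-best" when its
    magnitude is <= 2.
    """
    votes: dict = {}
    deltas = []
    th_lo, th_hi, alphas = [], [], []
    sums: dict = {}
    counts: dict = {}
    any_fit = False
    for fits in per_map_fits:
        win, runner = _winner(fits)
        if win is None:
            continue
        any_fit = True
        votes[win] = votes.get(win, 0) + 1
        if runner is not None:
            deltas.append(fits[win].aicc - fits[runner].aicc)
        for m, f in fits.items():
            if f is not None:
                sums[m] = sums.get(m, 0.0) + f.aicc
                counts[m] = counts.get(m, 0) + 1
        if fits.get("OUM") is not None:
            th_lo.append(fits["OUM"].params.theta_low)
            th_hi.append(fits["OUM"].params.theta_high)
    if not any_fit:
        raise ValueError("all model fits failed in every map")
    consensus = max(sorted(votes), key=lambda m: votes[m])
    for fits in per_map_fits:
        f = fits.get(consensus)
        if f is not None and f.params.alpha is not None:
            alphas.append(f.params.alpha)
    delta = float(np.median(deltas)) if deltas else 0.0
    support = "among-best" if abs(delta) <= EQUIVALENCE_DELTA else "clear"
    alpha = float(np.median(alphas)) if alphas else None
    return ModelComparison(
        consensus=consensus,
        support=support,
        delta_aicc=delta,
        votes=votes,
        theta_low=float(np.median(th_lo)) if th_lo else None,
        theta_high=float(np.median(th_hi)) if th_hi else None,
        alpha=alpha,
        halflife=half_life(alpha) if alpha else None,
        mean_aicc={m: sums[m] / counts[m] for m in sums},
        trait=trait,
        treatment=treatment,
    )


def half_life(alpha: float) -> float:
    """Phylogenetic half-life ln(2)/alpha, in mya for alpha per mya."""
    if alpha is None or alpha <= 0:
        raise ValueError("half-life requires alpha > 0")
    return float(np.log(2.0) / alpha)


def halflife_significant(mean: float, sd: float) -> bool:
    """Half-life significantly above zero: mean - 1.64*SD > 0."""
    return (mean - 1.64 * sd) > 0


def bootstrap_half_life(
    tree: Tree,
    data: "evomodels.TraitData",
    smaps=None,
    model_policy: str = "OU1",
    remove_fraction: float = 1.0 / 3.0,
    n_boot: int = 200,
    seed: int = 0,
):
    """Half-life uncertainty by random species removal.

    Each replicate drops ``floor(n * remove_fraction)`` random species,
    refits the policy model (OU1, or OUM — used when OUM is the best or
    among the best models) on the pruned tree, and records ln(2)/alpha.
    Returns (mean, SD, significant, replicate values); significance is
    mean - 1.64*SD > 0.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if model_policy not in ("OU1", "OUM"):
        raise ValueError("model_policy must be 'OU1' or 'OUM'")
    if model_policy == "OUM" and not smaps:
        raise ValueError("OUM policy requires stochastic maps")
    rng = np.random.default_rng(seed)
    labels = list(tree.tip_labels)
    n = len(labels)
    n_drop = int(np.floor(n * remove_fraction))
    values = []
    for _ in range(n_boot):
        keep = list(labels)
        if n_drop > 0:
            drop = set(rng.choice(n, size=n_drop, replace=False))
            keep = [lab for i, lab in enumerate(labels) if i not in drop]
        pr = prune_with_sources(tree, keep)
        sub_data = _subset_data(data, keep)
        smap = None
        if model_policy == "OUM":
            smap = carry_map(pr, smaps[rng.integers(len(smaps))])
        try:
            fit = evomodels.fit_evo_model(model_policy, pr.tree, smap, sub_data)
        except (ValueError, RuntimeError):
            continue
        if fit.params.alpha and fit.params.alpha > 0:
            values.append(half_life(fit.params.alpha))
    if len(values) < 2:
        raise RuntimeError("too few successful bootstrap refits")
    values = np.array(values)
    mean, sd = float(values.mean()), float(values.std(ddof=1))
    return mean, sd, halflife_significant(mean, sd), values


def _subset_data(data, keep):
    idx = {s: i for i, s in enumerate(data.species)}
    order = [idx[s] for s in keep]
    nr = None if data.n_rounds is None else np.asarray(data.n_rounds)[order]
    return evomodels.TraitData(tuple(keep), data.mean[order], data.se[order], nr)


def treatment_halflife_contrast(
    halflives: pd.DataFrame,
    baseline: str = "Mild",
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Growth-environment effect on evolutionary lability of traits.

    Fits a linear mixed model on log(t1/2) with treatment as a fixed factor
    (contrasts against ``baseline``) and trait as a random intercept, by
    maximum likelihood; intervals are 90% percentile bootstrap over traits.
    A contrast of log(0.5) ~ -0.693 corresponds to a 50% half-life
    reduction relative to baseline.

    ``halflives`` needs columns ``trait``, ``treatment``, ``halflife``.
    """
    import statsmodels.formula.api as smf

    df = halflives.copy()
    treatments = sorted(df["treatment"].unique())
    if len(treatments) < 2:
        raise ValueError("need at least 2 treatments")
    if df["trait"].nunique() < 3:
        raise ValueError("need at least 3 traits")
    if baseline not in treatments:
        raise ValueError(f"baseline {baseline!r} not present")
    df["loghl"] = np.log(df["halflife"])

    def fit(d):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(
                f"loghl ~ C(treatment, Treatment('{baseline}'))", d, groups=d["trait"]
            ).fit(reml=False)
        out = {}
        for name, val in m.fe_params.items():
            if "Treatment" in name:
                level = name.split("[T.")[-1].rstrip("]")
                out[level] = float(val)
        return out

    point = fit(df)
    rng = np.random.default_rng(seed)
    traits = sorted(df["trait"].unique())
    draws: dict = {lvl: [] for lvl in point}
    for _ in range(n_boot):
        pick = rng.choice(traits, size=len(traits), replace=True)
        parts = []
        for j, tr in enumerate(pick):
            part = df[df["trait"] == tr].copy()
            part["trait"] = f"boot{j}"  # resampled traits stay distinct groups
            parts.append(part)
        bd = pd.concat(parts, ignore_index=True)
        try:
            est = fit(bd)
        except Exception:
            continue
        for lvl in draws:
            if lvl in est:
                draws[lvl].append(est[lvl])
    rows = []
    for lvl, est in point.items():
        d = np.array(draws[lvl]) if draws[lvl] else np.array([est])
        rows.append(
            {
                "contrast": f"{lvl} vs {baseline}",
                "estimate": est,
                "lower90": float(np.percentile(d, 5)),
                "upper90": float(np.percentile(d, 95)),
            }
        )
    return pd.DataFrame(rows)
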