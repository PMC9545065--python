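"""Multi-trait screening: standardization, VIF pruning, DAPC, correlations.

The species x (trait, treatment) matrix is selectively log10-transformed and
z-scored (sample SD), stripped of highly collinear columns by iterative
variance-inflation-factor pruning (threshold 10), and then summarized by
discriminant analysis of principal components (DAPC): PCA scores feed a
two-group linear discriminant separating low- from high-elevation species,
with the number of retained PCs chosen by stratified cross-validation.
Variable contributions are the squared discriminant loadings mapped back to
trait space (summing to 1); traits above the third quartile of contributions
are screened for pairwise Pearson trade-off correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "TraitMatrix",
    "DapcResult",
    "standardize",
    "vif_prune",
    "dapc",
    "xval_pc_retention",
    "select_discriminating",
    "pearson_matrix",
]


@dataclass
class TraitMatrix:
    """Standardized species x trait-combination matrix with group labels."""

    data: pd.DataFrame  # rows = species, z-scored columns
    groups: pd.Series  # species -> "low" | "high"


def standardize(matrix: pd.DataFrame, log10_columns=()) -> pd.DataFrame:
    """Selective log10 transform, then per-column z-scores (sample SD).

    Columns listed in ``log10_columns`` must be strictly positive; a
    zero-variance column raises an error naming it.
    """
    out = matrix.copy().astype(float)
    for col in log10_columns:
        if col not in out.columns:
            raise KeyError(f"log10 column {col!r} not in matrix")
        if (out[col] <= 0).any():
            raise ValueError(f"log10 column {col!r} has non-positive values")
        out[col] = np.log10(out[col])
    sd = out.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    return (out - out.mean()) / sd


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R^2_j) regressing column j on the others (direct)."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        r = yj - Z @ coef
        ss_res = float(r @ r)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(matrix: pd.DataFrame, threshold: float = 10.0):
    """Iteratively drop the max-VIF column while any VIF exceeds threshold.

    Perfectly collinear columns have infinite VIF and go first; VIF ties
    break toward the earlier column in column order, making the outcome
    deterministic and independent of row order.  Returns
    (reduced matrix, list of dropped columns in drop order).
    """
    kept = matrix.copy()
    dropped = []
    while kept.shape[1] > 1:
        v = _vifs(kept.to_numpy(float))
        worst = int(np.argmax(v))  # argmax takes the first maximum: tie rule
        if v[worst] > threshold:
            dropped.append(kept.columns[worst])
            kept = kept.drop(columns=kept.columns[worst])
        else:
            break
    return kept, dropped


@dataclass
class DapcResult:
    n_pcs: int
    axis: np.ndarray  # discriminant direction in variable space
    contributions: pd.Series  # squared loadings, sum 1
    accuracy: float
    assignments: pd.Series  # species -> predicted group
    posterior: pd.Series  # species -> P(group == positive label)


def dapc(tm: TraitMatrix, n_pcs: int) -> DapcResult:
    """PCA -> retain ``n_pcs`` scores -> two-group linear discriminant.

    The discriminant vector is mapped back to variable space through the PC
    loadings; contributions are its squared entries normalized to sum 1.
    Accuracy is the in-sample fraction of species assigned to their group.
    """
    X = tm.data.to_numpy(float)
    y = tm.groups.loc[tm.data.index].to_numpy()
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank {rank}")
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(X)
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, y)
    pred = lda.predict(scores)
    accuracy = float(np.mean(pred == y))
    w = pca.components_.T @ lda.coef_[0]  # back to variable space
    contrib = w**2
    contrib = contrib / contrib.sum()
    pos = lda.classes_[1]
    post = lda.predict_proba(scores)[:, 1]
    return DapcResult(
        n_pcs=n_pcs,
        axis=w,
        contributions=pd.Series(contrib, index=tm.data.columns),
        accuracy=accuracy,
        assignments=pd.Series(pred, index=tm.data.index),
        posterior=pd.Series(post, index=tm.data.index, name=f"P({pos})"),
    )


def xval_pc_retention(
    tm: TraitMatrix,
    grid,
    reps: int = 100,
    holdout_fraction: float = 0.1,
    seed: int = 0,
) -> int:
    """Choose the PC count by repeated stratified holdout.

    Per grid level: hold out ``holdout_fraction`` of each group (at least one
    species), train the discriminant on the rest, score assignment success
    on the holdout.  The optimum minimizes the mean squared assignment error
    (1 - success)^2; ties break toward highest mean success, then fewer PCs.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty PC grid")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    X = tm.data.to_numpy(float)
    y = tm.groups.loc[tm.data.index].to_numpy()
    levels = np.unique(y)
    by_group = {g: np.where(y == g)[0] for g in levels}
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("each group needs at least 2 species")
    results = {}
    for n_pcs in grid:
        errs, succs = [], []
        for _ in range(reps):
            test_idx = []
            for g in levels:
                ids = by_group[g]
                k = max(1, int(round(holdout_fraction * len(ids))))
                test_idx.extend(rng.choice(ids, size=k, replace=False))
            test_idx = np.array(test_idx)
            train = np.setdiff1d(np.arange(len(y)), test_idx)
            pca = PCA(n_components=min(n_pcs, len(train) - 1))
            st = pca.fit_transform(X[train])
            lda = LinearDiscriminantAnalysis().fit(st, y[train])
            pred = lda.predict(pca.transform(X[test_idx]))
            success = float(np.mean(pred == y[test_idx]))
            succs.append(success)
            errs.append((1.0 - success) ** 2)
        results[n_pcs] = (float(np.mean(errs)), float(np.mean(succs)))
    return min(grid, key=lambda p: (results[p][0], -results[p][1], p))


def select_discriminating(result: DapcResult, quantile: float = 0.75) -> list:
    """Variables whose contribution exceeds the empirical contribution
    quantile (default the third quartile)."""
    cut = float(np.quantile(result.contributions.to_numpy(), quantile))
    return [c for c, v in result.contributions.items() if v > cut]


def pearson_matrix(matrix: pd.DataFrame, min_pairs: int = 3):
    """Pairwise-complete Pearson correlations with two-sided p-values.

    p comes from t = r sqrt((n-2)/(1-r^2)); cells with fewer than
    ``min_pairs`` complete pairs are NaN.  Returns (r, p, n, stars)
    DataFrames; stars at 0.05/0.01/0.001.
    """
    cols = matrix.columns
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    X = matrix.to_numpy(float)
    for i in range(k):
        for j in range(i, k):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            m = int(ok.sum())
            n[i, j] = n[j, i] = m
            if m < min_pairs:
                continue
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            ri, pi = sps.pearsonr(X[ok, i], X[ok, j])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi

    def star(pv):
        if not np.isfinite(pv):
            return ""
        if pv < 0.001:
            return "***"
        if pv < 0.01:
            return "**"
        if pv < 0.05:
            return "*"
        return ""

    stars = pd.DataFrame(
        [[star(p[i, j]) for j in range(k)] for i in range(k)], index=cols, columns=cols
    )
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        pd.DataFrame(n, index=cols, columns=cols),
        stars,
    )
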