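"""Growth-curve traits from individual plant records.

Leaf-length trajectories are summarized by a three-parameter logistic curve
y(t) = ASYM / (1 + exp((XMID - t)/scal)): asymptotic size ASYM (mm), time to
half the asymptotic size XMID (days), and scale scal (days), with the
maximal growth rate MGR = 1/scal (per day).  Because smaller XMID means
faster progression, analyses use (-)XMID.  Stress tolerance of a growth
parameter is its relative change under frost or heat versus the mild
treatment: (stress - mild)/mild.  Species-level values are hierarchical
means (plant -> species x treatment x round -> species x treatment) with the
between-round SD/sqrt(n_rounds) as the measurement error fed to the
evolutionary models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .evomodels import TraitData

__all__ = [
    "GrowthFit",
    "logistic",
    "fit_logistic",
    "initial_growth_rate",
    "negate_xmid",
    "tolerance",
    "aggregate_species_means",
]

TREATMENTS = ("Frost", "Mild", "Heat")


@dataclass(frozen=True)
class GrowthFit:
    asym: float  # mm
    xmid: float  # days
    scal: float  # days
    resid_sd: float
    converged: bool

    @property
    def mgr(self) -> float:
        """Maximal growth rate, 1/scal (per day)."""
        return 1.0 / self.scal

    @property
    def neg_xmid(self) -> float:
        return -self.xmid


def logistic(t, asym, xmid, scal):
    return asym / (1.0 + np.exp((xmid - t) / scal))


def fit_logistic(days, lengths) -> GrowthFit:
    """Least-squares three-parameter logistic fit with self-starting values.

    Starting values: ASYM0 = 1.05 * max(y); XMID0 = first day with
    y >= max(y)/2; scal0 from the 25-75% rise interval.  Fits on monotone
    non-saturating data that push ASYM to its bound come back flagged
    ``converged=False`` and are excluded from species means upstream.
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 observations for a logistic fit")
    if np.any(np.diff(t) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("lengths must be >= 0")
    if len(np.unique(t)) != len(t):
        warnings.warn("duplicate observation days shift the fit")
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("all lengths zero: nothing to fit")
    asym0 = 1.05 * ymax
    above = t[y >= ymax / 2.0]
    xmid0 = above[0] if len(above) else t[len(t) // 2]
    q25 = t[y >= 0.25 * ymax]
    q75 = t[y >= 0.75 * ymax]
    rise = (q75[0] - q25[0]) if len(q25) and len(q75) else (t[-1] - t[0]) / 4.0
    scal0 = max(rise / 2.2, 1e-2)  # logistic rises 25->75% over ~2.2 scal

    hi_asym = 100.0 * ymax

    def resid(p):
        return logistic(t, *p) - y

    res = least_squares(
        resid,
        x0=[asym0, xmid0, scal0],
        bounds=([1e-9, -10 * t[-1], 1e-6], [hi_asym, 10 * t[-1], 10 * t[-1]]),
        method="trf",
    )
    asym, xmid, scal = res.x
    dof = max(len(t) - 3, 1)
    resid_sd = float(np.sqrt(np.sum(res.fun**2) / dof))
    # an ASYM at the upper bound means the data never saturate
    converged = bool(res.success) and asym < 0.99 * hi_asym
    return GrowthFit(float(asym), float(xmid), float(scal), resid_sd, converged)


def initial_growth_rate(days, lengths, window_days: float = 7.0) -> float:
    """IGR (mm/day): OLS slope over observations within the first
    ``window_days`` of treatment; NaN when fewer than 2 points fall in the
    window."""
    t = np.asarray(days, dtype=float)
    y = np.asarray(lengths, dtype=float)
    sel = t <= window_days
    if sel.sum() < 2:
        return float("nan")
    slope = np.polyfit(t[sel], y[sel], 1)[0]
    return float(slope)


def negate_xmid(xmid: float) -> float:
    """(-)XMID: sign-flipped so larger values mean faster growth progression."""
    return -xmid


def tolerance(stress_estimate: float, mild_estimate: float) -> float:
    """Relative change under stress: (stress - mild)/mild.

    Undefined (NaN, with a warning) when the mild estimate is zero.
    """
    if mild_estimate == 0:
        warnings.warn("mild estimate is zero: tolerance undefined")
        return float("nan")
    return (stress_estimate - mild_estimate) / mild_estimate


def aggregate_species_means(records: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Hierarchical aggregation of per-plant trait values.

    ``records`` is long-format with columns ``species``, ``treatment``,
    ``round``, ``plant`` and a value column.  Plant replicates are averaged,
    then species x treatment x round, then across rounds; the SE attached is
    SD across round means / sqrt(n_rounds).  Species observed in a single
    round get SE = NaN here and the trait's median SE imputed by
    :func:`to_trait_data`.
    """
    per_plant = (
        records.groupby(["species", "treatment", "round", "plant"], sort=True)[value]
        .mean()
        .reset_index()
    )
    per_round = (
        per_plant.groupby(["species", "treatment", "round"], sort=True)[value]
        .mean()
        .reset_index()
    )
    out = (
        per_round.groupby(["species", "treatment"], sort=True)[value]
        .agg(mean="mean", sd="std", n_rounds="count")
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n_rounds"])
    return out.drop(columns="sd")


def to_trait_data(agg: pd.DataFrame, treatment: str) -> TraitData:
    """TraitData for one treatment; single-round species get the median SE."""
    sub = agg[agg["treatment"] == treatment].sort_values("species")
    se = sub["se"].to_numpy(dtype=float)
    med = np.nanmedian(se) if np.any(np.isfinite(se)) else 0.0
    imputed = ~np.isfinite(se)
    if imputed.any():
        warnings.warn(
            f"imputed median SE for {int(imputed.sum())} single-round species"
        )
        se = np.where(imputed, med, se)
    return TraitData(
        tuple(sub["species"]),
        sub["mean"].to_numpy(dtype=float),
        se,
        sub["n_rounds"].to_numpy(),
    )
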