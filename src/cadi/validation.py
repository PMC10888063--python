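"""Validation of the index against survey-based prevalence.

Computes the sampling-weighted prevalence of a mental-disorder indicator per
region and the Pearson, Kendall (tau-b) and Spearman correlations between
the index and prevalence across regions. With few paired regions (n <= 9 by
default) the p-values are exact permutation p-values over all n!
rearrangements; otherwise the usual asymptotic two-sided p-values are used.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["weighted_prevalence", "CorrelationReport", "correlation_suite"]


def weighted_prevalence(records: pd.DataFrame) -> pd.Series:
    """Weighted prevalence per region: sum(w * disorder) / sum(w).

    Records with a missing disorder status are dropped (listwise within
    region) before weighting. Weights must be strictly positive and the
    indicator binary.
    """
    if records.empty:
        return pd.Series(dtype=float, name="prevalence")
    recs = records.dropna(subset=["disorder"]).copy()
    if (recs["weight"] <= 0).any():
        raise ValueError("sampling weights must be strictly positive")
    if not recs["disorder"].isin([0, 1]).all():
        bad = sorted(set(recs["disorder"]) - {0, 1})
        raise ValueError(f"disorder indicator must be binary, found {bad}")
    num = (recs["weight"] * recs["disorder"]).groupby(recs["region"]).sum()
    den = recs["weight"].groupby(recs["region"]).sum()
    out = num / den
    out.name = "prevalence"
    return out


@dataclass
class CorrelationReport:
    """Three rank/linear association coefficients with two-sided p-values."""

    pearson: float
    kendall: float
    spearman: float
    p_pearson: float
    p_kendall: float
    p_spearman: float
    n: int
    method: str  # "exact-permutation" or "asymptotic"

    def to_dict(self) -> dict:
        return asdict(self)


def _pearson_stat(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between x and every row of Y (rows with zero variance -> nan)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (Yc * Yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Yc @ xc) / denom


def _kendall_stat(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Tie-corrected Kendall tau-b between x and every row of Y."""
    n = len(x)
    pairs = list(itertools.combinations(range(n), 2))
    sx = np.array([np.sign(x[i] - x[j]) for i, j in pairs])
    num = np.zeros(Y.shape[0])
    ty = np.zeros(Y.shape[0])               # tied pairs in each y
    for (i, j), s in zip(pairs, sx):
        d = np.sign(Y[:, i] - Y[:, j])
        num += s * d
        ty += d == 0
    n0 = len(pairs)
    tx = n0 - np.count_nonzero(sx)          # tied pairs in x
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / np.sqrt((n0 - tx) * (n0 - ty))


def _exact_permutation(x: np.ndarray, y: np.ndarray):
    """Exact two-sided permutation p-values for all three coefficients."""
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))))
    Y = y[perms]                           # (n!, n)
    rx = stats.rankdata(x)
    Ry = stats.rankdata(y)[perms]

    out = {}
    for name, stat_x, stat_Y in (
            ("pearson", x, Y),
            ("spearman", rx, Ry)):
        r_all = _pearson_stat(np.asarray(stat_x, dtype=float),
                              np.asarray(stat_Y, dtype=float))
        r_obs = r_all[0]
        p = np.mean(np.abs(r_all) >= np.abs(r_obs) - 1e-12)
        out[name] = (float(r_obs), float(p))
    t_all = _kendall_stat(x, Y.astype(float))
    t_obs = t_all[0]
    out["kendall"] = (float(t_obs),
                      float(np.mean(np.abs(t_all) >= np.abs(t_obs) - 1e-12)))
    return out


def correlation_suite(x, y, exact_max_n: int = 9) -> CorrelationReport:
    """Pearson, Kendall tau-b and Spearman coefficients with p-values.

    Pairs with a missing value in either vector are dropped (pairwise
    deletion). Zero variance in either vector leaves the coefficients
    undefined: they are reported as NaN with a warning, never coerced to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance in x or y: correlation undefined, "
                      "reporting NaN", stacklevel=2)
        nan = float("nan")
        return CorrelationReport(nan, nan, nan, nan, nan, nan, n, "undefined")

    # identity permutation must be first so the observed statistic is row 0
    if n <= exact_max_n:
        res = _exact_permutation(x, y)
        return CorrelationReport(
            pearson=res["pearson"][0], kendall=res["kendall"][0],
            spearman=res["spearman"][0], p_pearson=res["pearson"][1],
            p_kendall=res["kendall"][1], p_spearman=res["spearman"][1],
            n=n, method="exact-permutation")

    pr = stats.pearsonr(x, y)
    kt = stats.kendalltau(x, y, variant="b")
    sp = stats.spearmanr(x, y)
    return CorrelationReport(
        pearson=float(pr.statistic), kendall=float(kt.statistic),
        spearman=float(sp.statistic), p_pearson=float(pr.pvalue),
        p_kendall=float(kt.pvalue), p_spearman=float(sp.pvalue),
        n=n, method="asymptotic")
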