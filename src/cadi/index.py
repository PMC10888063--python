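"""Composite Anxiety and Depression Index (CADI) synthesis.

Given a Public Opinion Dictionary with relevance scores alpha(i), national and
regional search-trend series, regional populations and a national Internet
penetration series, the index for region r in year y is

    CADI(r, y) = sum_i [ (gb(r,i,y) - min_r gb) / (max_r gb - min_r gb)
                         * tau + (100 - tau) ] * w(i, y)

where gb(r,i,y) = gamma(r,i,y) / population(r,y) is the population-adjusted
yearly mean regional trend of word i, the min/max run over all regions within
the same (word, year) cell, and the word weights

    w(i, y) = phi(i, y) / sum_i phi(i, y),   phi(i, y) = alpha(i) * beta(i, y)

combine relevance with the national yearly mean trend beta. This is the
efficacy-coefficient linear weighting scheme: with the default tau = 40 each
per-word score lies in [60, 100] and so does their convex combination.
A final year-over-year rescaling by the Internet-penetration ratio
pi(y)/pi(y-1) makes the index comparable across years.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "NATIONAL_REGION", "yearly_average", "aggregate_yearly", "split_national",
    "compute_weights", "population_adjust", "efficacy_score", "compute_cadi",
    "penetration_adjust", "CADIModel",
]

#: Region label whose trend rows carry the national series (feeds beta).
NATIONAL_REGION = "NATIONAL"


def yearly_average(series: pd.DataFrame, year: int,
                   label: str = "series") -> float:
    """Arithmetic mean of the observations falling in a calendar year.

    ``series`` has columns (date, value); missing days are simply absent
    from the mean. Raises if the year has no observation.
    """
    dates = pd.to_datetime(series["date"])
    values = series.loc[dates.dt.year == int(year), "value"]
    if values.empty:
        raise ValueError(f"no observations in year {year} for {label}")
    return float(values.mean())


def aggregate_yearly(trends: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long (region, word, date, value) panel to yearly means.

    Returns columns (region, word, year, value), one row per cell that has
    at least one observation.
    """
    out = trends.copy()
    out["year"] = pd.to_datetime(out["date"]).dt.year
    out = (out.groupby(["region", "word", "year"], observed=True, sort=True)
              ["value"].mean().reset_index())
    return out


def split_national(yearly: pd.DataFrame,
                   national_region: str = NATIONAL_REGION):
    """Split yearly means into the national beta table and the regional panel."""
    is_nat = yearly["region"].astype(str) == national_region
    national = (yearly.loc[is_nat, ["word", "year", "value"]]
                .rename(columns={"value": "beta"}).reset_index(drop=True))
    regional = (yearly.loc[~is_nat]
                .rename(columns={"value": "gamma"}).reset_index(drop=True))
    return national, regional


def compute_weights(pod: pd.DataFrame, national: pd.DataFrame) -> pd.DataFrame:
    """Yearly word weights w(i,y) = alpha(i)*beta(i,y) / sum_i alpha*beta.

    Every POD word must have a national trend for every year; within each
    year the weights sum to one.
    """
    merged = pod[["word", "alpha"]].merge(national[["word", "year", "beta"]],
                                          on="word", how="left")
    missing = merged[merged["beta"].isna()]
    if not missing.empty:
        words = sorted(missing["word"].unique())
        raise ValueError(
            f"POD words without a national trend series: {words}")
    years = sorted(national["year"].unique())
    covered = merged.groupby("word")["year"].nunique()
    short = sorted(covered[covered < len(years)].index)
    if short:
        raise ValueError(
            f"POD words missing a national trend in some year: {short}")

    merged["phi"] = merged["alpha"] * merged["beta"]
    totals = merged.groupby("year")["phi"].transform("sum")
    bad_years = sorted(merged.loc[totals <= 0, "year"].unique())
    if bad_years:
        raise ValueError(
            f"sum of phi is zero in year(s) {bad_years}: every word is "
            "either irrelevant (alpha=0) or untrended (beta=0)")
    merged["w"] = merged["phi"] / totals
    return merged[["word", "year", "phi", "w"]].sort_values(
        ["year", "word"], kind="mergesort").reset_index(drop=True)


def population_adjust(panel: pd.DataFrame,
                      population: pd.DataFrame) -> pd.DataFrame:
    """Per-person trend gb = gamma / population, joined on (region, year)."""
    pop = population.rename(columns={"population": "delta"})
    if (pop["delta"] <= 0).any():
        bad = pop.loc[pop["delta"] <= 0, ["region", "year"]].values.tolist()
        raise ValueError(f"non-positive population for (region, year): {bad}")
    out = panel.merge(pop[["region", "year", "delta"]],
                      on=["region", "year"], how="left")
    missing = out[out["delta"].isna()]
    if not missing.empty:
        keys = sorted({(r, int(y)) for r, y in
                       missing[["region", "year"]].itertuples(index=False)})
        raise ValueError(f"missing population rows for (region, year): {keys}")
    out["gamma_bar"] = out["gamma"] / out["delta"]
    return out.drop(columns="delta")


def efficacy_score(value: float, lo: float, hi: float, tau: float) -> float:
    """Efficacy-coefficient score of one indicator value.

    Maps [lo, hi] linearly onto [100 - tau, 100]. When hi == lo (the
    indicator does not separate regions) the midpoint 100 - tau/2 is
    returned so the indicator stays in the aggregation but carries no
    regional information.
    """
    if not 0.0 < tau <= 100.0:
        raise ValueError(f"tau must lie in (0, 100], got {tau}")
    if not lo <= value <= hi:
        raise ValueError(f"value {value} outside [{lo}, {hi}]")
    if hi == lo:
        return (100.0 - tau) + tau / 2.0
    return (value - lo) / (hi - lo) * tau + (100.0 - tau)


def compute_cadi(panel: pd.DataFrame, weights: pd.DataFrame,
                 tau: float = 40.0) -> pd.DataFrame:
    """Aggregate population-adjusted trends into the per-region-year index.

    ``panel`` needs columns (region, word, year, gamma_bar) and must be
    balanced: every (word, year) covered by ``weights`` must be observed in
    every region. The min/max envelope of each (word, year) cell is taken
    over all regions, including the region being scored.
    """
    if not 0.0 < tau <= 100.0:
        raise ValueError(f"tau must lie in (0, 100], got {tau}")
    regions = sorted(panel["region"].astype(str).unique())
    if len(regions) < 2:
        raise ValueError("CADI needs at least 2 regions for min-max scaling")

    rows = []
    for year, wy in weights.groupby("year"):
        sub = panel[panel["year"] == year]
        grid = sub.pivot_table(index="region", columns="word",
                               values="gamma_bar", aggfunc="first")
        words = list(wy["word"])
        missing_words = [w for w in words if w not in grid.columns]
        if missing_words:
            raise ValueError(
                f"unbalanced panel: year {year} lacks any observation for "
                f"word(s) {missing_words}")
        grid = grid.reindex(index=regions, columns=words)
        if grid.isna().any().any():
            holes = [(r, w) for r, w in
                     zip(*np.where(grid.isna().values))]
            named = [(regions[r], words[w]) for r, w in holes[:10]]
            raise ValueError(
                f"unbalanced panel in year {year}: missing (region, word) "
                f"cells, e.g. {named}")
        g = grid.values
        lo, hi = g.min(axis=0), g.max(axis=0)
        span = hi - lo
        frac = np.where(span > 0, (g - lo) / np.where(span > 0, span, 1.0), 0.5)
        scores = frac * tau + (100.0 - tau)
        w = wy["w"].values
        cadi = scores @ w
        rows.append(pd.DataFrame({"region": regions, "year": int(year),
                                  "cadi": cadi}))
    out = pd.concat(rows, ignore_index=True)
    out["tau"] = float(tau)
    return out.sort_values(["year", "region"], kind="mergesort").reset_index(drop=True)


def penetration_adjust(cadi: pd.DataFrame,
                       penetration: pd.DataFrame) -> pd.DataFrame:
    """Rescale the index by the year-over-year Internet-penetration ratio.

    cadi_adjusted(r, y) = cadi(r, y) * pi(y) / pi(y-1); the first year of
    the span has no predecessor and uses ratio 1. The adjustment is applied
    with the adjacent-year ratio exactly, not compounded from a base year.
    """
    pen = penetration.set_index("year")["penetration"]
    if (pen <= 0).any():
        raise ValueError("penetration values must be strictly positive")
    years = sorted(cadi["year"].unique())
    first = years[0]
    ratio = {}
    for y in years:
        if y == first:
            ratio[y] = 1.0
            continue
        if y not in pen.index or (y - 1) not in pen.index:
            raise ValueError(
                f"penetration missing for year {y} or {y - 1}; cannot form "
                "the adjacent-year ratio")
        ratio[y] = float(pen[y] / pen[y - 1])
    out = cadi.copy()
    out["cadi_adjusted"] = out["cadi"] * out["year"].map(ratio)
    return out


class CADIModel(BaseEstimator):
    """Estimator wrapper for the full trend-to-index computation.

    ``fit`` consumes the long trend table (rows labelled ``NATIONAL`` feed
    the national means beta), the POD, the population table and optionally
    the penetration series; the fitted index is in ``cadi_``.

    Attributes
    ----------
    weights_ : DataFrame (word, year, phi, w)
    panel_ : DataFrame, the population-adjusted regional yearly panel
    cadi_ : DataFrame (region, year, cadi, tau[, cadi_adjusted])
    """

    def __init__(self, tau: float = 40.0,
                 national_region: str = NATIONAL_REGION):
        self.tau = tau
        self.national_region = national_region

    def fit(self, trends: pd.DataFrame, pod: pd.DataFrame,
            population: pd.DataFrame,
            penetration: Optional[pd.DataFrame] = None) -> "CADIModel":
        yearly = aggregate_yearly(trends)
        national, regional = split_national(yearly, self.national_region)
        if national.empty:
            raise ValueError(
                f"no national trend rows (region == {self.national_region!r})")
        regional = regional[regional["word"].isin(pod["word"])]
        self.weights_ = compute_weights(pod, national)
        self.panel_ = population_adjust(regional, population)
        cadi = compute_cadi(self.panel_, self.weights_, tau=self.tau)
        if penetration is not None:
            cadi = penetration_adjust(cadi, penetration)
        self.cadi_ = cadi
        return self
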