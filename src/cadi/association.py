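"""Association between the index and economic / medical covariates.

Pools the regional panel (index response, eight covariates, year dummies
with the earliest year as reference) and fits an ordinary least squares
model (LRM) and a median regression (QRM, check-loss at quantile 0.50,
robust to outliers). Regions are additionally partitioned into low / high
per-capita-GDP subgroups at the multi-year national mean — each region is
assigned wholly by its own multi-year mean, ties to the high group — and
both models are refit within each subgroup, yielding the familiar
six-column coefficient grid with significance stars.

QRM standard errors are bootstrap (case resampling, 500 replicates by
default, fixed seed); OLS uses conventional standard errors. Covariates are
not standardised, so coefficients are on the raw scales of the supplied
columns; set ``standardize=True`` on :class:`AssociationAnalysis` to z-score
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .synthetic import COVARIATE_NAMES

__all__ = [
    "RegressionResult", "build_design", "fit_lrm", "fit_qrm",
    "split_by_gdp", "run_full_analysis", "AssociationAnalysis",
    "significance_stars", "format_results_table",
]

INTERCEPT = "_cons"


@dataclass
class RegressionResult:
    """Fitted coefficients with inference, one model on one sample."""

    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: Optional[float]
    n: int
    model_kind: str              # "LRM" or "QRM"
    quantile: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "std_errors": self.std_errors.to_dict(),
            "p_values": self.p_values.to_dict(),
            "r_squared": self.r_squared,
            "n": self.n,
            "model_kind": self.model_kind,
            "quantile": self.quantile,
        }


def _find_dependent_columns(X: np.ndarray, names: Sequence[str]) -> list:
    """Columns that do not increase the rank of the preceding ones."""
    dependent, kept = [], np.empty((X.shape[0], 0))
    rank = 0
    for j, name in enumerate(names):
        cand = np.hstack([kept, X[:, j:j + 1]])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            dependent.append(name)
    return dependent


def build_design(panel: pd.DataFrame,
                 covariates: Sequence[str] = COVARIATE_NAMES,
                 response: str = "cadi"):
    """Design matrix (intercept, covariates, year dummies) and response.

    Year dummies use reference coding with the earliest year as the
    reference, one indicator per later year; a single-year panel simply has
    no dummy columns. Row order is preserved. Collinear columns raise,
    naming the dependent columns.
    """
    missing = [c for c in (*covariates, response, "year") if c not in panel]
    if missing:
        raise ValueError(f"panel lacks required column(s): {missing}")
    if panel[list(covariates) + [response]].isna().any().any():
        raise ValueError("modeled columns contain missing values")

    X = pd.DataFrame({INTERCEPT: np.ones(len(panel), dtype=float)},
                     index=panel.index)
    for c in covariates:
        X[c] = panel[c].astype(float)
    years = sorted(panel["year"].unique())
    for y in years[1:]:
        X[f"year_{y}"] = (panel["year"] == y).astype(float)
    y_vec = panel[response].astype(float)

    dependent = _find_dependent_columns(X.values, list(X.columns))
    if dependent:
        raise ValueError(f"collinear design columns: {dependent}")
    return X, y_vec


def fit_lrm(X: pd.DataFrame, y: pd.Series) -> RegressionResult:
    """Ordinary least squares with conventional (non-robust) inference."""
    if len(X) <= X.shape[1]:
        raise ValueError(
            f"need more rows ({len(X)}) than columns ({X.shape[1]})")
    dependent = _find_dependent_columns(np.asarray(X, dtype=float),
                                        list(X.columns))
    if dependent:
        raise ValueError(f"rank-deficient design; dependent columns: "
                         f"{dependent}")
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return RegressionResult(
        coefficients=pd.Series(fit.params, index=X.columns),
        std_errors=pd.Series(fit.bse, index=X.columns),
        p_values=pd.Series(fit.pvalues, index=X.columns),
        r_squared=float(fit.rsquared), n=len(X), model_kind="LRM")


def check_loss(residuals: np.ndarray, q: float) -> float:
    """Quantile-regression objective: sum of rho_q over residuals."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (q - (r < 0))))


def _qr_point_estimate(X: pd.DataFrame, y: np.ndarray, q: float,
                       max_iter: int) -> np.ndarray:
    """Coefficients minimising the check loss.

    A constant-only design reduces to the sample quantile and is solved
    directly (for q = 0.5 and even n this is the midpoint convention of
    the median); otherwise statsmodels' iteratively reweighted least
    squares is used and non-convergence raises.
    """
    cols = np.asarray(X, dtype=float)
    if cols.shape[1] == 1 and np.ptp(cols[:, 0]) == 0:
        return np.array([float(np.quantile(y, q)) / cols[0, 0]])
    with warnings.catch_warnings():
        warnings.simplefilter("error", IterationLimitWarning)
        try:
            fit = sm.QuantReg(y, X).fit(q=q, max_iter=max_iter)
        except IterationLimitWarning as exc:
            raise RuntimeError(
                f"quantile regression did not converge within "
                f"{max_iter} iterations (q={q}, n={len(y)}): {exc}") from exc
    return np.asarray(fit.params, dtype=float)


def fit_qrm(X: pd.DataFrame, y: pd.Series, q: float = 0.50,
            se_method: str = "bootstrap", n_boot: int = 500,
            seed: int = 0, max_iter: int = 2000) -> RegressionResult:
    """Quantile regression at quantile ``q`` (default: median).

    Standard errors come from case-resampling bootstrap (``n_boot``
    replicates, deterministic under ``seed``); ``se_method="asymptotic"``
    uses statsmodels' kernel-based covariance instead. p-values are normal
    approximations on coef/se.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    if len(X) <= X.shape[1]:
        raise ValueError(
            f"need more rows ({len(X)}) than columns ({X.shape[1]})")
    y_arr = np.asarray(y, dtype=float)
    params = _qr_point_estimate(X, y_arr, q, max_iter)

    if se_method == "asymptotic" and X.shape[1] > 1:
        fit = sm.QuantReg(y_arr, X).fit(q=q, max_iter=max_iter)
        bse = np.asarray(fit.bse, dtype=float)
    else:
        rng = np.random.default_rng(seed)
        n = len(y_arr)
        Xv = np.asarray(X, dtype=float)
        draws, failures = [], 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                draws.append(_qr_point_estimate(
                    pd.DataFrame(Xv[idx], columns=X.columns),
                    y_arr[idx], q, max_iter))
            except (RuntimeError, np.linalg.LinAlgError, ValueError):
                failures += 1
        if len(draws) < n_boot // 2:
            raise RuntimeError(
                f"bootstrap unstable: {failures}/{n_boot} resamples failed")
        bse = np.std(np.vstack(draws), axis=0, ddof=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = params / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return RegressionResult(
        coefficients=pd.Series(params, index=X.columns),
        std_errors=pd.Series(bse, index=X.columns),
        p_values=pd.Series(pvals, index=X.columns),
        r_squared=None, n=len(X), model_kind="QRM", quantile=q)


def split_by_gdp(panel: pd.DataFrame):
    """Partition regions into low / high per-capita-GDP subgroups.

    The threshold is the mean of ``gdp_pc`` over all rows (the multi-year
    national average); a region goes wholly to subgroup1 if its own
    multi-year mean is below the threshold, else to subgroup2 (ties high).
    Regions are never split across groups.
    """
    if "gdp_pc" not in panel or panel["gdp_pc"].isna().any():
        raise ValueError("gdp_pc must be present for every row")
    threshold = panel["gdp_pc"].mean()
    region_means = panel.groupby("region")["gdp_pc"].mean()
    low = region_means.index[region_means < threshold]
    sub1 = panel[panel["region"].isin(low)].copy()
    sub2 = panel[~panel["region"].isin(low)].copy()
    if sub1.empty or sub2.empty:
        warnings.warn("all regions fall on one side of the GDP threshold; "
                      "one subgroup is empty", stacklevel=2)
    return sub1, sub2


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def run_full_analysis(panel: pd.DataFrame,
                      covariates: Sequence[str] = COVARIATE_NAMES,
                      response: str = "cadi", q: float = 0.50,
                      n_boot: int = 500, seed: int = 0) -> dict:
    """Fit LRM and QRM on the overall panel and both GDP subgroups.

    Returns ``{(group, kind): RegressionResult}`` with groups "Overall",
    "Subgroup1", "Subgroup2" and kinds "LRM", "QRM". An empty subgroup
    is reported as None for both its models.
    """
    sub1, sub2 = split_by_gdp(panel)
    results = {}
    for group, data in (("Overall", panel), ("Subgroup1", sub1),
                        ("Subgroup2", sub2)):
        if data.empty:
            results[(group, "LRM")] = None
            results[(group, "QRM")] = None
            continue
        X, y = build_design(data, covariates=covariates, response=response)
        results[(group, "LRM")] = fit_lrm(X, y)
        results[(group, "QRM")] = fit_qrm(X, y, q=q, n_boot=n_boot, seed=seed)
    return results


def format_results_table(results: dict) -> pd.DataFrame:
    """Render the six-model grid as coefficient strings with stars.

    Rows are the union of coefficient names (plus R-squared and n);
    columns are (kind, group) pairs in the conventional order.
    """
    order = [("LRM", g) for g in ("Overall", "Subgroup1", "Subgroup2")] + \
            [("QRM", g) for g in ("Overall", "Subgroup1", "Subgroup2")]
    terms: list = []
    for res in results.values():
        if res is not None:
            for t in res.coefficients.index:
                if t not in terms:
                    terms.append(t)
    # intercept conventionally printed last
    if INTERCEPT in terms:
        terms = [t for t in terms if t != INTERCEPT] + [INTERCEPT]

    table = pd.DataFrame(index=terms + ["R-squared", "n"],
                         columns=pd.MultiIndex.from_tuples(order),
                         dtype=object)
    for (group, kind), res in results.items():
        col = (kind, group)
        if res is None:
            table[col] = "-"
            continue
        for t in terms:
            if t in res.coefficients.index:
                table.loc[t, col] = (f"{res.coefficients[t]:.3f}"
                                     f"{significance_stars(res.p_values[t])}")
            else:
                table.loc[t, col] = "-"
        table.loc["R-squared", col] = (f"{res.r_squared:.3f}"
                                       if res.r_squared is not None else "-")
        table.loc["n", col] = str(res.n)
    return table


class AssociationAnalysis(BaseEstimator):
    """Estimator running the full six-model association analysis.

    Parameters
    ----------
    quantile : float, default 0.50
        Quantile for the QRM fits.
    n_boot : int, default 500
        Bootstrap replicates for QRM standard errors.
    standardize : bool, default False
        z-score the covariates before fitting (coefficients then per-sd).
    seed : int, default 0

    Attributes
    ----------
    results_ : dict (group, kind) -> RegressionResult
    table_ : DataFrame, formatted coefficient grid with stars
    """

    def __init__(self, quantile: float = 0.50, n_boot: int = 500,
                 standardize: bool = False, subgroups: bool = True,
                 covariates: Sequence[str] = COVARIATE_NAMES,
                 response: str = "cadi", seed: int = 0):
        self.quantile = quantile
        self.n_boot = n_boot
        self.standardize = standardize
        self.subgroups = subgroups
        self.covariates = covariates
        self.response = response
        self.seed = seed

    def fit(self, panel: pd.DataFrame, y=None) -> "AssociationAnalysis":
        data = panel.copy()
        if self.standardize:
            for c in self.covariates:
                sd = data[c].std(ddof=0)
                data[c] = (data[c] - data[c].mean()) / (sd if sd > 0 else 1.0)
        if self.subgroups:
            self.results_ = run_full_analysis(
                data, covariates=self.covariates, response=self.response,
                q=self.quantile, n_boot=self.n_boot, seed=self.seed)
        else:
            X, yv = build_design(data, covariates=self.covariates,
                                 response=self.response)
            self.results_ = {
                ("Overall", "LRM"): fit_lrm(X, yv),
                ("Overall", "QRM"): fit_qrm(X, yv, q=self.quantile,
                                            n_boot=self.n_boot,
                                            seed=self.seed),
            }
        self.table_ = format_results_table(self.results_)
        return self
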