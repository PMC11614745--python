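"""Annotation-map association: receptor regression with dominance analysis
and cognitive-term correlation profiles.

Dominance analysis decomposes a multiple regression's explained variance into
per-predictor contributions by averaging the incremental R-squared of adding a
predictor across all 2^p - 1 predictor subsets.  The average is level-weighted
(mean over subset sizes of the mean increment at that size), which guarantees
that per-predictor total dominances sum exactly to the full model's R-squared.
Interactional dominance is the increment when the predictor joins the submodel
containing all others.  Percent contribution normalises total dominance by its
sum, so it is invariant to whether ordinary or adjusted R-squared is used as
the normaliser.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DataError, ParameterError

__all__ = [
    "RegressionFit",
    "DominanceResult",
    "TermCorrelationTable",
    "fit_receptor_model",
    "dominance_analysis",
    "term_correlation",
]


@dataclass
class RegressionFit:
    coefficients: np.ndarray  # per predictor, standardized scale
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    n_observations: int
    n_predictors: int


@dataclass
class DominanceResult:
    predictors: list[str]
    total_dominance: np.ndarray
    interactional_dominance: np.ndarray
    percent_contribution: np.ndarray
    full_model_r2: float
    full_model_adjusted_r2: float

    def ranking(self) -> list[str]:
        order = np.argsort(self.percent_contribution)[::-1]
        return [self.predictors[i] for i in order]


@dataclass
class TermCorrelationTable:
    table: pd.DataFrame  # columns: term, rho, flagged

    @property
    def flagged_terms(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "term"].tolist()


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise DataError(f"constant predictor column(s): {np.flatnonzero(sd == 0).tolist()}")
    return (X - X.mean(axis=0)) / sd


def fit_receptor_model(y: np.ndarray, X: np.ndarray | pd.DataFrame) -> RegressionFit:
    """OLS of a cortical map on standardized predictor maps."""
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n <= p + 1:
        raise ParameterError("need n > p + 1 observations")
    Xs = _standardize(Xa)
    if np.linalg.matrix_rank(Xs) < p:
        corr = np.corrcoef(Xs, rowvar=False)
        np.fill_diagonal(corr, 0)
        worst = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise DataError(f"rank-deficient design; most collinear columns {worst}")
    model = sm.OLS(y, sm.add_constant(Xs)).fit()
    return RegressionFit(coefficients=np.asarray(model.params[1:]),
                         intercept=float(model.params[0]),
                         r_squared=float(model.rsquared),
                         adjusted_r_squared=float(model.rsquared_adj),
                         n_observations=n, n_predictors=p)


def _subset_r2_all(Xs: np.ndarray, y: np.ndarray) -> dict[int, float]:
    """Ordinary R-squared of every non-empty predictor subset, keyed by bitmask.

    Uses the centred Gram matrix so each submodel is a small SPD solve.
    """
    n, p = Xs.shape
    yc = y - y.mean()
    syy = float(yc @ yc)
    G = Xs.T @ Xs  # predictors are standardized (mean 0), so this is centred
    gy = Xs.T @ yc
    r2 = {0: 0.0}
    idx_of = [1 << j for j in range(p)]
    for size in range(1, p + 1):
        for combo in combinations(range(p), size):
            mask = 0
            for j in combo:
                mask |= idx_of[j]
            ci = list(combo)
            g_sub = gy[ci]
            beta = np.linalg.solve(G[np.ix_(ci, ci)], g_sub)
            r2[mask] = float(g_sub @ beta) / syy
    return r2


def dominance_analysis(y: np.ndarray, X: np.ndarray | pd.DataFrame,
                       level_weighted: bool = True) -> DominanceResult:
    """Complete dominance decomposition over all 2^p - 1 submodels.

    ``level_weighted=True`` (default) averages incremental R-squared first
    within each subset size and then across sizes, which makes the total
    dominances sum exactly to the full-model R-squared.  The uniform average
    over all subsets is available for comparison with ``level_weighted=False``
    (it does not satisfy the summation identity).
    """
    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else [f"x{j + 1}" for j in range(np.asarray(X).shape[1])])
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if p > 20:
        raise ParameterError(
            f"p = {p} predictors means {2 ** p - 1} submodels; dominance "
            "analysis is limited to p <= 20 — reduce the predictor set")
    if n <= p + 1:
        raise ParameterError("need n > p + 1 observations")
    Xs = _standardize(Xa)
    if np.linalg.matrix_rank(Xs) < p:
        raise DataError("rank-deficient predictor matrix")

    r2 = _subset_r2_all(Xs, y)
    full_mask = (1 << p) - 1
    full_r2 = r2[full_mask]
    adj = 1 - (1 - full_r2) * (n - 1) / (n - p - 1)

    total = np.empty(p)
    inter = np.empty(p)
    for j in range(p):
        bit = 1 << j
        inc_by_size: dict[int, list[float]] = {s: [] for s in range(p)}
        for mask, base in r2.items():
            if mask & bit:
                continue
            size = mask.bit_count()
            inc_by_size[size].append(r2[mask | bit] - base)
        if level_weighted:
            total[j] = float(np.mean([np.mean(v) for v in inc_by_size.values()]))
        else:
            total[j] = float(np.mean([x for v in inc_by_size.values() for x in v]))
        inter[j] = r2[full_mask] - r2[full_mask & ~bit]
    denom = total.sum()
    percent = total / denom * 100.0 if denom != 0 else np.zeros(p)
    return DominanceResult(predictors=names, total_dominance=total,
                           interactional_dominance=inter,
                           percent_contribution=percent,
                           full_model_r2=full_r2, full_model_adjusted_r2=float(adj))


def term_correlation(cortical_map: np.ndarray, term_maps: pd.DataFrame,
                     top_fraction: float = 0.1) -> TermCorrelationTable:
    """Spearman correlation of a cortical map with each z-scored term map.

    The ``floor(top_fraction * T)`` terms with the largest rho are flagged
    (123 terms at 10 % flag exactly 12).  Boundary ties break by term-name
    lexical order, so the output is deterministic.  Constant term maps get
    NaN and are never flagged.
    """
    cortical_map = np.asarray(cortical_map, dtype=float)
    if term_maps.shape[1] < 1:
        raise ParameterError("need at least one term map")
    if not (0.0 < top_fraction <= 1.0):
        raise ParameterError("top_fraction must lie in (0, 1]")
    rows = []
    for term in term_maps.columns:
        v = term_maps[term].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            rows.append((term, np.nan))
            continue
        z = (v - v.mean()) / v.std()
        rows.append((term, float(stats.spearmanr(cortical_map, z)[0])))
    df = pd.DataFrame(rows, columns=["term", "rho"])
    n_flag = int(np.floor(top_fraction * len(df)))
    order = df.sort_values(["rho", "term"], ascending=[False, True],
                           na_position="last").index
    flagged = np.zeros(len(df), dtype=bool)
    flagged[order[:n_flag]] = True
    df["flagged"] = flagged
    return TermCorrelationTable(df)
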