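"""Per-site predictors and predictive models of long-term species loss.

Candidate predictors of a site's conservation value (the proportional
regional species loss its removal causes): the fraction of regional biomass
it holds (a proxy for area), its compositional distinctness (mean Bray-
Curtis dissimilarity to all other sites), and four standard network
centralities of the spatial graph. Predictive power is assessed by
exhaustive OLS model selection under AIC with z-scored predictors, variance
partitioning between area and distinctness, and Spearman rank correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

__all__ = [
    "PREDICTORS",
    "RegressionReport",
    "bray_curtis",
    "distinctness",
    "centralities",
    "fit_models",
    "variance_partition",
    "extinction_timing_stats",
]

PREDICTORS = ["biomass_fraction", "distinctness", "degree", "closeness",
              "betweenness", "eigenvector"]


def bray_curtis(b_x: np.ndarray, b_y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    b_x = np.asarray(b_x, dtype=float)
    b_y = np.asarray(b_y, dtype=float)
    denom = float((b_x + b_y).sum())
    if denom == 0.0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(b_x - b_y).sum() / denom)


def distinctness(biomass: np.ndarray) -> np.ndarray:
    """Mean Bray-Curtis dissimilarity of each site to all other sites.

    ``biomass`` is the S x N species-by-site matrix; column x is site x's
    composition.
    """
    biomass = np.asarray(biomass, dtype=float)
    n = biomass.shape[1]
    if n < 2:
        raise ValueError("need at least 2 sites")
    if (biomass.sum(axis=0) == 0).any():
        raise ValueError("empty site composition: Bray-Curtis undefined")
    d = squareform(pdist(biomass.T, metric="braycurtis"))
    return d.sum(axis=1) / (n - 1)


def centralities(adjacency: np.ndarray) -> pd.DataFrame:
    """Degree, closeness, betweenness and eigenvector centrality per site.

    Closeness uses the harmonic-mean generalisation on disconnected graphs;
    eigenvector centrality is the principal eigenvector of the adjacency
    matrix normalised to maximum 1.
    """
    adjacency = np.asarray(adjacency)
    g = nx.from_numpy_array(adjacency)
    n = adjacency.shape[0]
    deg = np.array([d for _, d in sorted(g.degree())], dtype=float)
    if nx.is_connected(g):
        clo = np.array([nx.closeness_centrality(g)[i] for i in range(n)])
    else:
        clo = np.array([nx.harmonic_centrality(g)[i] for i in range(n)]) / max(n - 1, 1)
    bet = np.array([nx.betweenness_centrality(g)[i] for i in range(n)])
    vals, vecs = np.linalg.eigh(adjacency.astype(float))
    ev = np.abs(vecs[:, np.argmax(vals)])
    ev = ev / ev.max() if ev.max() > 0 else ev
    return pd.DataFrame({"degree": deg, "closeness": clo,
                         "betweenness": bet, "eigenvector": ev})


@dataclass
class RegressionReport:
    selected: tuple[str, ...]
    coefficients: dict               # standardised coefficients of selected model
    aic: dict                        # AIC per candidate model (key: predictor tuple)
    adj_r2_full: float               # area + distinctness model
    adj_r2_area: float
    adj_r2_distinctness: float
    adj_r2_selected: float
    partition: dict                  # unique_area, unique_distinctness, shared, residual
    spearman: dict                   # rho per predictor vs response
    n_rows: int = 0


def _aic(rss: float, n: int, k: int) -> float:
    # n*ln(RSS/n) + 2*(k+1); k = number of predictors (intercept adds one)
    return n * np.log(rss / n) + 2 * (k + 1)


def _ols_r2(y: np.ndarray, x: np.ndarray | None) -> tuple[float, float, np.ndarray]:
    """Returns (R^2, adjusted R^2, params) of an OLS fit with intercept."""
    design = sm.add_constant(x) if x is not None and x.shape[1] else \
        np.ones((len(y), 1))
    fit = sm.OLS(y, design).fit()
    r2 = float(fit.rsquared) if design.shape[1] > 1 else 0.0
    adj = float(fit.rsquared_adj) if design.shape[1] > 1 else 0.0
    return r2, adj, fit.params


def variance_partition(table: pd.DataFrame, response: str = "value") -> dict:
    """Partition R^2 of the area+distinctness model by nested differences.

    unique_area + unique_distinctness + shared = R^2_full exactly (on
    unadjusted R^2); residual = 1 - R^2_full.
    """
    y = table[response].to_numpy(dtype=float)
    za = _zscore(table["biomass_fraction"].to_numpy(dtype=float))
    zd = _zscore(table["distinctness"].to_numpy(dtype=float))
    r2_full, _, _ = _ols_r2(y, np.column_stack([za, zd]))
    r2_a, _, _ = _ols_r2(y, za[:, None])
    r2_d, _, _ = _ols_r2(y, zd[:, None])
    return {
        "unique_area": r2_full - r2_d,
        "unique_distinctness": r2_full - r2_a,
        "shared": r2_a + r2_d - r2_full,
        "residual": 1.0 - r2_full,
        "r2_full": r2_full,
    }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def fit_models(table: pd.DataFrame, response: str = "value",
               predictors: list[str] | None = None) -> RegressionReport:
    """Exhaustive OLS subset selection under AIC with z-scored predictors.

    Ties in AIC are broken toward fewer predictors (then lexicographically).
    Constant (zero-variance) predictors are dropped with a note, as aliased.
    """
    predictors = list(predictors or PREDICTORS)
    if len(table) < 10:
        raise ValueError("need at least 10 rows to fit predictive models")
    y = table[response].to_numpy(dtype=float)
    n = len(y)
    cols = {}
    for p in predictors:
        z = _zscore(table[p].to_numpy(dtype=float))
        if z.std() > 0:
            cols[p] = z
    usable = list(cols)
    aic = {}
    best = None
    for k in range(len(usable) + 1):
        for subset in itertools.combinations(usable, k):
            if subset:
                x = np.column_stack([np.ones(n)] + [cols[p] for p in subset])
                beta, *_ = np.linalg.lstsq(x, y, rcond=None)
                rss = float(np.sum((y - x @ beta) ** 2))
            else:
                rss = float(np.sum((y - y.mean()) ** 2))
            a = _aic(max(rss, 1e-300), n, len(subset))
            aic[subset] = a
            key = (round(a, 10), len(subset), subset)
            if best is None or key < best[0]:
                best = (key, subset)
    selected = best[1]
    sel_design = sm.add_constant(np.column_stack([cols[p] for p in selected])) \
        if selected else np.ones((n, 1))
    sel_fit = sm.OLS(y, sel_design).fit()
    coeffs = {p: float(c) for p, c in zip(("intercept",) + selected, sel_fit.params)}

    _, adj_full, _ = _ols_r2(y, np.column_stack([cols[p] for p in
                                                 ("biomass_fraction", "distinctness")
                                                 if p in cols]))
    _, adj_area, _ = _ols_r2(y, cols["biomass_fraction"][:, None]
                             if "biomass_fraction" in cols else None)
    _, adj_dist, _ = _ols_r2(y, cols["distinctness"][:, None]
                             if "distinctness" in cols else None)
    adj_sel = float(sel_fit.rsquared_adj) if selected else 0.0
    rho = {}
    for p in predictors:
        r = spearmanr(table[p].to_numpy(dtype=float), y).statistic
        rho[p] = float(r) if np.isfinite(r) else np.nan
    return RegressionReport(
        selected=selected,
        coefficients=coeffs,
        aic=aic,
        adj_r2_full=adj_full,
        adj_r2_area=adj_area,
        adj_r2_distinctness=adj_dist,
        adj_r2_selected=adj_sel,
        partition=variance_partition(table, response),
        spearman=rho,
        n_rows=n,
    )


def extinction_timing_stats(records: pd.DataFrame) -> dict:
    """Timing/distance summary over pooled extinction records.

    ``records`` needs columns ``time`` (unit times since removal) and
    ``distance_frac`` (last-detection distance in units of L). Lag strata:
    within 50 unit times, beyond 50, and beyond 120.
    """
    if len(records) == 0:
        return {"n": 0}
    t = records["time"].to_numpy(dtype=float)
    d = records["distance_frac"].to_numpy(dtype=float)
    early = t <= 50
    late = t > 50
    very_late = t > 120
    times = np.sort(t)

    def _mean(mask):
        return float(d[mask].mean()) if mask.any() else np.nan

    return {
        "n": int(len(t)),
        "mean_distance": float(d.mean()),
        "mean_distance_leq50": _mean(early),
        "mean_distance_gt50": _mean(late),
        "mean_distance_gt120": _mean(very_late),
        "n_leq50": int(early.sum()),
        "n_gt50": int(late.sum()),
        "n_gt120": int(very_late.sum()),
        "cumulative_times": times,
        "cumulative_fraction": np.arange(1, len(times) + 1) / len(times),
    }
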