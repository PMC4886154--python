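"""Homogeneity analysis (Gifi) of nominal item responses, plus scale statistics.

Homogeneity analysis — multiple correspondence analysis in its alternating
least squares formulation — places individuals (object scores) and item answer
categories (category quantifications) in a joint p-dimensional space,
minimizing the average squared distance between each individual and the
categories they chose:

    loss(X, Y) = (1/k) sum_j || X - G_j Y_j ||^2

with G_j the indicator matrix of item j, X the n x p object scores (centered,
unit variance per dimension) and Y_j the 3 x p category quantifications.
Category quantifications are the centroids of the individuals choosing that
category.  Here it serves to separate items that discriminate liberal versus
conservative respondents from items that mainly separate "?" answerers from
the rest, and to drive the item-selection rule for the reduced scale.

Classical reliability statistics (Cronbach's alpha, Guttman's lambda-2,
item-total correlations) are provided for the resulting sum scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "IndicatorMatrix",
    "build_indicator",
    "HomogeneityAnalysis",
    "fit_homogeneity",
    "category_points",
    "select_items",
    "ReliabilityReport",
    "reliability_stats",
    "cronbach_alpha",
    "guttman_lambda2",
    "loading_missing_regression",
]

N_CATEGORIES = 3


@dataclass
class IndicatorMatrix:
    """Complete-case binary indicator of category memberships (n x 3k)."""

    matrix: np.ndarray
    items: list[str]             # retained item column names
    row_ids: np.ndarray          # index labels of retained rows
    n_dropped_rows: int
    dropped_items: list[str]

    @property
    def n_items(self) -> int:
        return len(self.items)


def _extract_items(data, items=None) -> pd.DataFrame:
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data))
        data.columns = [f"item_{j + 1}" for j in range(data.shape[1])]
    if items is None:
        cols = [c for c in data.columns if str(c).startswith("item_")]
        if not cols:
            cols = list(data.columns)
    else:
        cols = [data.columns[i] if isinstance(i, (int, np.integer)) else i
                for i in items]
    return data[cols]


def build_indicator(data, items=None) -> IndicatorMatrix:
    """Build the complete-case indicator matrix for the selected items.

    Rows with any missing scored item are dropped; items in which only a
    single category was observed are degenerate (their indicator block has
    rank 0 after centering) and are dropped with a warning.
    """
    df = _extract_items(data, items)
    y = df.to_numpy(dtype=float, na_value=np.nan)
    keep = ~np.isnan(y).any(axis=1)
    n_dropped = int((~keep).sum())
    y = y[keep].astype(int)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 complete-case rows")
    if y.size and (y.min() < 0 or y.max() > 2):
        raise ValueError("responses must be coded 0, 1, 2")

    retained, dropped = [], []
    for j, name in enumerate(df.columns):
        if np.unique(y[:, j]).size < 2:
            dropped.append(str(name))
            warnings.warn(f"item {name!r} has a single observed category; dropped")
        else:
            retained.append(j)
    if not retained:
        raise ValueError("no non-degenerate items left")
    y = y[:, retained]
    n, k = y.shape
    G = np.zeros((n, k * N_CATEGORIES))
    for j in range(k):
        G[np.arange(n), j * N_CATEGORIES + y[:, j]] = 1.0
    return IndicatorMatrix(G, [str(df.columns[j]) for j in retained],
                           np.asarray(df.index[keep]), n_dropped, dropped)


class HomogeneityAnalysis(BaseEstimator):
    """Alternating-least-squares homogeneity analysis (nominal Gifi/MCA).

    Parameters
    ----------
    n_dimensions : int
        Dimensions p of the joint space.
    max_iter, tol : ALS stopping rule (relative loss change).

    Attributes
    ----------
    eigenvalues_ : (p,) discrimination eigenvalues, non-increasing.
    object_scores_ : (n, p) centered scores with unit variance per dimension.
    quantifications_ : dict item -> (3, p) category quantification matrix.
    loadings_ : (k, p) correlation of each item's quantified scores with each
        object-score dimension.
    loss_trace_ : per-iteration loss values (non-increasing).

    Notes
    -----
    Initialization is deterministic (SVD of the centered indicator), and the
    final solution is rotated to principal axes, so repeated runs agree.
    The eigenvalue scale follows the unit-variance object-score convention
    and is comparable only within this package.
    """

    def __init__(self, n_dimensions: int = 2, max_iter: int = 500, tol: float = 1e-8):
        self.n_dimensions = n_dimensions
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        ind = X if isinstance(X, IndicatorMatrix) else build_indicator(X)
        G = ind.matrix
        n, kc = G.shape
        k = kc // N_CATEGORIES
        p = self.n_dimensions
        if p < 1 or p > kc - k:
            raise ValueError(f"n_dimensions must be in [1, {kc - k}]")

        counts = G.sum(axis=0)                       # per-category counts
        Gc = G - counts / n                          # centered indicator
        # deterministic init: leading left singular vectors
        U, _, _ = np.linalg.svd(Gc, full_matrices=False)
        Xs = U[:, :p] * np.sqrt(n)
        Xs -= Xs.mean(axis=0)

        inv_counts = 1.0 / counts
        loss_trace: list[float] = []
        prev = np.inf
        converged = False
        for _ in range(self.max_iter):
            Y = (G.T @ Xs) * inv_counts[:, None]     # category centroids
            GY = G @ Y                                # (n, p) per item summed? no:
            # G @ Y sums G_j Y_j over items, so the per-item residual loss is
            # sum_j ||X||^2 - 2 <X, G_j Y_j> + ||G_j Y_j||^2 accumulated below.
            sq = (Y * Y * counts[:, None]).sum()      # sum_j ||G_j Y_j||^2
            loss = (k * (Xs * Xs).sum() - 2.0 * (Xs * GY).sum() + sq) / k
            loss_trace.append(loss)
            if prev - loss <= self.tol * max(abs(loss), 1.0):
                converged = True
                break
            prev = loss
            Xt = GY / k
            Xt -= Xt.mean(axis=0)
            U, _, Vt = np.linalg.svd(Xt, full_matrices=False)
            Xs = np.sqrt(n) * (U @ Vt)               # constrained least squares
        if not converged:
            raise RuntimeError(
                f"ALS did not converge in {self.max_iter} iterations; "
                f"loss trace tail: {loss_trace[-5:]}")

        # rotate to principal axes: align object scores with the singular
        # directions of the averaged centroid matrix, sorting dimensions
        Y = (G.T @ Xs) * inv_counts[:, None]
        Xt = G @ Y / k
        Xt -= Xt.mean(axis=0)
        U, _, _ = np.linalg.svd(Xt, full_matrices=False)
        Xs = np.sqrt(n) * U[:, :p]
        Xs -= Xs.mean(axis=0)
        Y = (G.T @ Xs) * inv_counts[:, None]

        eig = np.einsum("cp,c->p", Y * Y, counts) / (n * k)
        order = np.argsort(-eig)
        eig = eig[order]
        Xs = Xs[:, order]
        Y = Y[:, order]

        loadings = np.empty((k, p))
        quant: dict[str, np.ndarray] = {}
        for j in range(k):
            block = slice(j * N_CATEGORIES, (j + 1) * N_CATEGORIES)
            Yj = Y[block]
            quant[ind.items[j]] = Yj
            qscores = G[:, block] @ Yj               # (n, p) quantified item
            for s in range(p):
                sd = qscores[:, s].std()
                loadings[j, s] = (0.0 if sd == 0 else
                                  np.corrcoef(qscores[:, s], Xs[:, s])[0, 1])

        self.indicator_ = ind
        self.eigenvalues_ = eig
        self.object_scores_ = Xs
        self.quantifications_ = quant
        self.loadings_ = loadings
        self.loss_trace_ = loss_trace
        self.n_iter_ = len(loss_trace)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).object_scores_


def fit_homogeneity(indicator, ndim: int = 2, max_iter: int = 500,
                    tol: float = 1e-8) -> HomogeneityAnalysis:
    """Fit a homogeneity solution; thin estimator wrapper."""
    return HomogeneityAnalysis(n_dimensions=ndim, max_iter=max_iter, tol=tol).fit(indicator)


def category_points(solution: HomogeneityAnalysis, item, ordinal_dim: int = 1):
    """Category quantification points of one item and an ordinality check.

    Each point is the centre of gravity of the individuals who chose that
    category.  Returns ``(points, is_ordinal)`` where ``points`` is (3, p) for
    "no", "?", "yes" and ``is_ordinal`` is True when the "?" coordinate lies
    between the "no" and "yes" coordinates on dimension ``ordinal_dim`` —
    the prerequisite for treating the item as ordinal in a partial credit
    model.
    """
    if isinstance(item, (int, np.integer)):
        item = solution.indicator_.items[item]
    if item not in solution.quantifications_:
        raise KeyError(f"unknown item {item!r}")
    pts = solution.quantifications_[item]
    no, q, yes = pts[0, ordinal_dim], pts[1, ordinal_dim], pts[2, ordinal_dim]
    is_ordinal = bool(min(no, yes) <= q <= max(no, yes))
    return pts, is_ordinal


def select_items(loadings, dim_keep: int = 1, dim_drop: int = 0) -> np.ndarray:
    """Indices of items loading (in absolute value) more on one dimension.

    Retains item j when |loading[j, dim_keep]| > |loading[j, dim_drop]|,
    strictly — ties are excluded.  With the package's dimension ordering this
    keeps trait-discriminating items and drops "?"-driven items.
    """
    L = np.abs(np.asarray(loadings, dtype=float))
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("loadings must have at least 2 dimensions")
    return np.flatnonzero(L[:, dim_keep] > L[:, dim_drop])


def cronbach_alpha(cov: np.ndarray) -> float:
    """Cronbach's alpha from an item covariance matrix."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    total = cov.sum()
    if total <= 0:
        raise ValueError("total score variance must be positive")
    return k / (k - 1.0) * (1.0 - np.trace(cov) / total)


def guttman_lambda2(cov: np.ndarray) -> float:
    """Guttman's lambda-2 from an item covariance matrix (>= alpha always)."""
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    total = cov.sum()
    if total <= 0:
        raise ValueError("total score variance must be positive")
    off = cov - np.diag(np.diag(cov))
    return (off.sum() + np.sqrt(k / (k - 1.0) * (off ** 2).sum())) / total


@dataclass
class ReliabilityReport:
    """Classical reliability statistics of a sum scale."""

    cronbach_alpha: float
    guttman_lambda2: float
    item_total: np.ndarray       # per-item correlation with the total score
    n_complete: int
    rest_score: bool             # True: item-rest (corrected) correlations


def reliability_stats(data, items=None, reverse_items=(), rest_score: bool = False) -> ReliabilityReport:
    """Cronbach's alpha, Guttman's lambda-2 and item-total correlations.

    Complete-case; reverse-keyed items (0-based positions within the selected
    item columns) are recoded x -> 2 - x first.  ``rest_score=True`` correlates
    each item with the total excluding itself.
    """
    df = _extract_items(data, items)
    y = df.to_numpy(dtype=float, na_value=np.nan)
    y = y[~np.isnan(y).any(axis=1)]
    if y.shape[1] < 2:
        raise ValueError("need at least 2 items")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 complete cases")
    rev = np.asarray(sorted(reverse_items), dtype=int)
    if rev.size:
        y[:, rev] = 2.0 - y[:, rev]
    cov = np.cov(y, rowvar=False, ddof=1)
    total = y.sum(axis=1)
    itc = np.empty(y.shape[1])
    for j in range(y.shape[1]):
        ref = total - y[:, j] if rest_score else total
        itc[j] = np.corrcoef(y[:, j], ref)[0, 1]
    return ReliabilityReport(cronbach_alpha(cov), guttman_lambda2(cov), itc,
                             y.shape[0], rest_score)


def loading_missing_regression(loadings, prop_question) -> pd.DataFrame:
    """Regress item loadings on each item's proportion of "?" answers.

    Ordinary least squares per dimension, t statistic on the slope with
    k - 2 degrees of freedom.  A strongly positive slope on a dimension marks
    it as driven by "?"-answering rather than the substantive trait.
    """
    import statsmodels.api as sm

    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    if L.shape[0] == 1:
        L = L.T
    x = np.asarray(prop_question, dtype=float)
    if L.shape[0] < 3:
        raise ValueError("need at least 3 items")
    if np.ptp(x) == 0:
        raise ValueError("proportion of '?' answers is constant across items")
    X = sm.add_constant(x)
    rows = []
    for s in range(L.shape[1]):
        res = sm.OLS(L[:, s], X).fit()
        rows.append({"dimension": s + 1, "slope": res.params[1],
                     "t": res.tvalues[1], "p": res.pvalues[1],
                     "df": int(res.df_resid), "r_squared": res.rsquared})
    return pd.DataFrame(rows)
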