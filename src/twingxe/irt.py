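"""Generalized partial credit model (GPCM) evaluation of a polytomous scale.

Implements the three-category GPCM used throughout the package: an individual
with latent trait ``theta`` "steps through" the ordered categories no -> ? ->
yes, with unnormalized weights

    w0 = 1,  w1 = exp(a (theta - b1)),  w2 = w1 * exp(a (theta - b2)),

and category probabilities ``w_c / (w0 + w1 + w2)``.  The PCM is the
restriction with all discriminations a = 1.

Marginal maximum likelihood fitting uses Bock-Aitkin EM over Gauss-Hermite
quadrature with the trait fixed at N(0, 1) for identification (the standard
convention of MML software).  The Bayesian joint model in
:mod:`twingxe.biometric` instead fixes one item's discrimination to 1;
:func:`rescale_item_params` converts estimates between the two conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .params import ItemParams

__all__ = [
    "gpcm_category_probs",
    "gpcm_logprob_matrix",
    "gpcm_response_loglik",
    "GeneralizedPartialCredit",
    "fit_mml",
    "information_criteria",
    "item_fit_chisq",
    "ItemFitResult",
    "rescale_item_params",
]


def _gpcm_logprobs(theta: np.ndarray, alpha, b1, b2) -> np.ndarray:
    """Log category probabilities, shape ``broadcast(theta, item) x 3``.

    Numerically stable: works in log space with an explicit running maximum.
    """
    t1 = alpha * (theta - b1)
    t12 = t1 + alpha * (theta - b2)
    m = np.maximum(0.0, np.maximum(t1, t12))
    logz = m + np.log(np.exp(-m) + np.exp(t1 - m) + np.exp(t12 - m))
    return np.stack([-logz, t1 - logz, t12 - logz], axis=-1)


def gpcm_category_probs(theta, item: ItemParams | None = None, *, alpha=None, b1=None, b2=None):
    """Probabilities of the categories "no" (0), "?" (1), "yes" (2).

    Parameters
    ----------
    theta : float or array
        Latent trait value(s).
    item : ItemParams, optional
        Item parameters; alternatively pass ``alpha``, ``b1``, ``b2`` directly
        (arrays broadcast against ``theta``).

    Returns
    -------
    ndarray with a trailing axis of length 3, rows summing to 1.
    """
    if item is not None:
        alpha, b1, b2 = item.alpha, item.b1, item.b2
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("discrimination must be positive")
    theta = np.asarray(theta, dtype=float)
    return np.exp(_gpcm_logprobs(theta, alpha, b1, b2))


def gpcm_logprob_matrix(theta: np.ndarray, alphas, b1s, b2s) -> np.ndarray:
    """Log probabilities for every (person, item, category).

    ``theta`` has shape (n,), item parameter arrays shape (k,); result is
    (n, k, 3).
    """
    theta = np.asarray(theta, dtype=float)[:, None]
    return _gpcm_logprobs(theta, np.asarray(alphas), np.asarray(b1s), np.asarray(b2s))


def gpcm_response_loglik(theta, responses, alphas, b1s, b2s) -> np.ndarray:
    """Per-person GPCM log likelihood of observed responses.

    ``responses`` is an (n, k) integer array with -1 marking missing cells;
    missing cells contribute nothing.  Returns shape (n,).
    """
    theta = np.asarray(theta, dtype=float)[:, None]
    a = np.asarray(alphas)
    t1 = a * (theta - np.asarray(b1s))
    t12 = t1 + a * (theta - np.asarray(b2s))
    m = np.maximum(0.0, np.maximum(t1, t12))
    logz = m + np.log(np.exp(-m) + np.exp(t1 - m) + np.exp(t12 - m))
    w = np.where(responses == 1, t1, 0.0)
    w = np.where(responses == 2, t12, w)
    contrib = w - logz
    return np.where(responses >= 0, contrib, 0.0).sum(axis=1)


def _as_response_matrix(data) -> np.ndarray:
    """Coerce a DataFrame/array of categories to int codes with -1 = missing."""
    import pandas as pd

    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float, na_value=np.nan)
    else:
        arr = np.asarray(data, dtype=float)
    out = np.where(np.isnan(arr), -1, arr).astype(np.int64)
    valid = (out >= -1) & (out <= 2)
    if not valid.all():
        raise ValueError("responses must be 0, 1, 2 or missing")
    return out


class GeneralizedPartialCredit(BaseEstimator):
    """GPCM / PCM fitted by marginal maximum likelihood (Bock-Aitkin EM).

    Parameters
    ----------
    model : {"GPCM", "PCM"}
        PCM fixes every discrimination to 1.
    n_quadrature : int
        Gauss-Hermite nodes for the N(0, 1) trait integral (default 61).
    max_iter, tol : EM stopping rule (absolute log-likelihood change).

    Attributes
    ----------
    items_ : tuple of ItemParams, estimated parameters per item.
    loglik_ : float, marginal log likelihood at the estimate.
    n_params_ : int, 3k for GPCM, 2k for PCM.
    n_obs_ : int, number of individuals used.
    converged_ : bool
    loglik_trace_ : list of per-EM-iteration marginal log likelihoods.
    """

    def __init__(self, model: str = "GPCM", n_quadrature: int = 61,
                 max_iter: int = 1000, tol: float = 1e-5):
        self.model = model
        self.n_quadrature = n_quadrature
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ---------------------------------------------------------

    def _quad(self):
        x, w = hermegauss(self.n_quadrature)
        w = w / w.sum()
        return x, w

    def _person_posterior(self, y, alphas, b1s, b2s, nodes, logw):
        """Posterior over nodes per person and the marginal log likelihood."""
        k = y.shape[1]
        logp = gpcm_logprob_matrix(nodes, alphas, b1s, b2s)  # (q, k, 3)
        ll = np.zeros((y.shape[0], nodes.size))
        for j in range(k):
            obs = y[:, j] >= 0
            if obs.any():
                ll[obs] += logp[:, j, :][:, y[obs, j]].T
        ll += logw
        m = ll.max(axis=1, keepdims=True)
        p = np.exp(ll - m)
        tot = p.sum(axis=1, keepdims=True)
        marg = float((np.log(tot) + m).sum())
        return p / tot, marg

    @staticmethod
    def _item_objective(params, r, nodes, pcm):
        """Negative expected complete-data log likelihood and gradient."""
        if pcm:
            a = 1.0
            b1, b2 = params
        else:
            a = np.exp(params[0])
            b1, b2 = params[1], params[2]
        s1 = nodes - b1
        s2 = nodes - b2
        t1 = a * s1
        t12 = t1 + a * s2
        m = np.maximum(0.0, np.maximum(t1, t12))
        logz = m + np.log(np.exp(-m) + np.exp(t1 - m) + np.exp(t12 - m))
        logp = np.stack([-logz, t1 - logz, t12 - logz], axis=-1)
        f = -float((r * logp).sum())
        # gradient: d/dp sum r_c (logw_c - logZ); dlogZ/dp = E_p[dlogw/dp]
        p = np.exp(logp)
        n_q = r.sum(axis=1)
        # d logw / d b1 = [0, -a, -a]; d / d b2 = [0, 0, -a]
        g_b1 = -(-a * (r[:, 1] + r[:, 2]) + a * n_q * (p[:, 1] + p[:, 2])).sum()
        g_b2 = -(-a * r[:, 2] + a * n_q * p[:, 2]).sum()
        if pcm:
            return f, np.array([g_b1, g_b2])
        # d logw / d log a = a * [0, s1, s1 + s2]
        dw = np.stack([np.zeros_like(s1), a * s1, a * (s1 + s2)], axis=-1)
        g_la = -((r * dw).sum() - (n_q * (p * dw).sum(axis=1)).sum())
        return f, np.array([g_la, g_b1, g_b2])

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit by EM.  ``X``: (n, k) categories 0/1/2, NaN (or -1) missing."""
        if self.model not in ("GPCM", "PCM"):
            raise ValueError(f"model must be 'GPCM' or 'PCM', got {self.model!r}")
        Y = _as_response_matrix(X)
        n, k = Y.shape
        if k < 2:
            raise ValueError("need at least 2 items")
        for j in range(k):
            obs = Y[:, j][Y[:, j] >= 0]
            if np.unique(obs).size < 2:
                raise ValueError(f"item {j} has fewer than 2 observed categories")
        pcm = self.model == "PCM"
        nodes, w = self._quad()
        logw = np.log(w)

        alphas = np.ones(k)
        b1s = np.zeros(k)
        b2s = np.zeros(k)
        trace: list[float] = []
        prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            post, marg = self._person_posterior(Y, alphas, b1s, b2s, nodes, logw)
            trace.append(marg)
            if abs(marg - prev) < self.tol:
                converged = True
                break
            prev = marg
            for j in range(k):
                r = np.zeros((nodes.size, 3))
                for c in range(3):
                    sel = Y[:, j] == c
                    if sel.any():
                        r[:, c] = post[sel].sum(axis=0)
                x0 = ([b1s[j], b2s[j]] if pcm
                      else [np.log(alphas[j]), b1s[j], b2s[j]])
                res = optimize.minimize(self._item_objective, x0,
                                        args=(r, nodes, pcm), jac=True,
                                        method="L-BFGS-B")
                if pcm:
                    b1s[j], b2s[j] = res.x
                else:
                    alphas[j] = np.exp(res.x[0])
                    b1s[j], b2s[j] = res.x[1], res.x[2]
        else:
            raise RuntimeError(
                f"EM did not converge in {self.max_iter} iterations; "
                f"log-likelihood trace tail: {trace[-5:]}")

        self.items_ = tuple(ItemParams(alphas[j], b1s[j], b2s[j]) for j in range(k))
        self.alphas_ = alphas
        self.b1_ = b1s
        self.b2_ = b2s
        self.loglik_ = trace[-1]
        self.loglik_trace_ = trace
        self.n_params_ = (2 * k) if pcm else (3 * k)
        self.n_obs_ = n
        self.converged_ = converged
        self._nodes = nodes
        self._logw = logw
        return self

    def eap_scores(self, X) -> np.ndarray:
        """Posterior-mean (EAP) trait estimate per individual."""
        Y = _as_response_matrix(X)
        post, _ = self._person_posterior(Y, self.alphas_, self.b1_, self.b2_,
                                         self._nodes, self._logw)
        return post @ self._nodes

    def score(self, X, y=None) -> float:
        """Marginal log likelihood of new data under the fitted items."""
        Y = _as_response_matrix(X)
        _, marg = self._person_posterior(Y, self.alphas_, self.b1_, self.b2_,
                                         self._nodes, self._logw)
        return marg


def fit_mml(data, model: str = "GPCM", quad_points: int = 61) -> GeneralizedPartialCredit:
    """Fit a GPCM or PCM by marginal maximum likelihood; thin estimator wrapper."""
    return GeneralizedPartialCredit(model=model, n_quadrature=quad_points).fit(data)


def information_criteria(fit: GeneralizedPartialCredit, n: int | None = None):
    """(AIC, BIC) of a fitted model: -2 l + 2 m and -2 l + m log n."""
    n = fit.n_obs_ if n is None else n
    aic = -2.0 * fit.loglik_ + 2.0 * fit.n_params_
    bic = -2.0 * fit.loglik_ + fit.n_params_ * np.log(n)
    return aic, bic


@dataclass
class ItemFitResult:
    """Binned chi-square item fit over equal-frequency total-score bins."""

    chisq: np.ndarray          # (k,)
    df: int
    p: np.ndarray              # (k,)
    bin_edges: np.ndarray      # (n_bins + 1,) total-score boundaries
    observed: np.ndarray       # (k, n_bins, 3)
    expected: np.ndarray       # (k, n_bins, 3)


def _score_distribution(P: np.ndarray) -> np.ndarray:
    """Lord-Wingersky recursion: P is (k, q, 3); returns (q, 2k + 1) with the
    conditional probability of each total score at each quadrature node."""
    q = P.shape[1]
    S = np.ones((q, 1))
    for j in range(P.shape[0]):
        new = np.zeros((q, S.shape[1] + 2))
        for c in range(3):
            new[:, c:c + S.shape[1]] += S * P[j, :, c][:, None]
        S = new
    return S


def item_fit_chisq(fit: GeneralizedPartialCredit, data, n_bins: int = 10,
                   expected_floor: float = 1e-6) -> ItemFitResult:
    """Observed versus model-expected category counts across total-score bins.

    Complete cases are grouped into (up to) ``n_bins`` equal-frequency bins of
    total score.  Expected category frequencies are conditional on the total
    score under the fitted model, computed exactly with the Lord-Wingersky
    recursion over the remaining items (the score-conditional construction
    that keeps the statistic calibrated despite the part-whole dependence of
    an item on its own total score).  df = n_bins * 2 - m_item with m_item
    the free parameters per item; tied score values can merge bins, in which
    case df uses the realized bin count.
    """
    Y = _as_response_matrix(data)
    Y = Y[(Y >= 0).all(axis=1)]
    n, k = Y.shape
    if n < n_bins:
        raise ValueError("fewer complete cases than bins")
    total = Y.sum(axis=1)
    max_score = 2 * k
    n_s = np.bincount(total, minlength=max_score + 1)

    nodes, w = fit._nodes, np.exp(fit._logw)
    P = np.exp(gpcm_logprob_matrix(nodes, fit.alphas_, fit.b1_, fit.b2_)
               ).transpose(1, 0, 2)                      # (k, q, 3)

    # equal-frequency grouping of adjacent score values
    import pandas as pd

    binned = pd.qcut(total, min(n_bins, np.unique(total).size),
                     duplicates="drop")
    codes = binned.codes
    realized = codes.max() + 1
    edges = np.unique(np.asarray(binned.categories.right, dtype=float))
    edges = np.concatenate([[float(total.min())], edges])

    observed = np.zeros((k, realized, 3))
    expected = np.zeros((k, realized, 3))
    bin_of_score = np.full(max_score + 1, -1)
    for s in np.unique(total):
        bin_of_score[s] = codes[total == s][0]

    for j in range(k):
        others = [i for i in range(k) if i != j]
        S_rest = _score_distribution(P[others])           # (q, 2k - 1)
        # joint P(score = s, y_j = c) integrated over the N(0,1) trait
        joint = np.zeros((max_score + 1, 3))
        for c in range(3):
            contrib = (w[:, None] * P[j, :, c][:, None] * S_rest).sum(axis=0)
            joint[c:c + S_rest.shape[1], c] += contrib
        p_s = joint.sum(axis=1)
        cond = np.divide(joint, p_s[:, None], out=np.full_like(joint, 1 / 3),
                         where=p_s[:, None] > 0)
        for s in np.unique(total):
            b = bin_of_score[s]
            expected[j, b] += n_s[s] * cond[s]
            for c in range(3):
                observed[j, b, c] += ((total == s) & (Y[:, j] == c)).sum()

    e = np.maximum(expected, expected_floor)
    chisq = ((observed - expected) ** 2 / e).sum(axis=(1, 2))
    m_item = 2 if fit.model == "PCM" else 3
    df = realized * 2 - m_item
    pvals = stats.chi2.sf(chisq, df)
    return ItemFitResult(chisq=chisq, df=df, p=pvals, bin_edges=edges,
                         observed=observed, expected=expected)


def rescale_item_params(items: Sequence[ItemParams], ref_index: int = 2):
    """Convert N(0,1)-trait estimates to the fixed-discrimination convention.

    Rescales the trait so the reference item's discrimination is 1 (the
    identification used by the Bayesian joint model): theta' = a_ref * theta,
    a'_k = a_k / a_ref, b'_k = a_ref * b_k.  Returns (items', trait_variance')
    where trait_variance' = a_ref**2 is the implied trait variance.
    """
    a_ref = items[ref_index].alpha
    out = tuple(ItemParams(it.alpha / a_ref, a_ref * it.b1, a_ref * it.b2, it.name)
                for it in items)
    return out, a_ref ** 2
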