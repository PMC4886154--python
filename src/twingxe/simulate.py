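"""Synthetic twin families with genotype-moderated environmental variances.

Generative model for the latent liberalism trait theta of twin j in family i:

MZ pairs (genetically identical, A shared):
    A_i  ~ N(0, sigma2_A)
    C_i  ~ N(0, exp(gamma0 + gamma1 A_i))          shared
    th_ij ~ N(A_i + C_i, exp(beta0 + beta1 A_i))   independent per twin

DZ pairs (genetic correlation 1/2, built hierarchically):
    A1_i  ~ N(0, sigma2_A / 2)
    A2_ij ~ N(A1_i, sigma2_A / 2)                  per twin
    C_i   ~ N(0, 1)                                shared standard-normal
    C2_ij = C_i * sqrt(exp(gamma0 + gamma1 A2_ij)) scaled per twin
    th_ij ~ N(A2_ij + C2_ij, exp(beta0 + beta1 A2_ij))

Item responses are then drawn from the three-category GPCM, and cells are
independently masked missing-at-random.  The default family counts (2795 MZ,
3280 DZ) and 9-item parameters emulate the Virginia 30K liberalism-scale twin
data, which are not publicly deposited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .irt import gpcm_category_probs, gpcm_logprob_matrix
from .params import GeneratingParams, ItemParams

__all__ = [
    "LatentFamily",
    "draw_mz_family",
    "draw_dz_family",
    "draw_mz_families",
    "draw_dz_families",
    "sample_gpcm_response",
    "simulate_dataset",
    "compute_sum_scores",
]


@dataclass(frozen=True)
class LatentFamily:
    """Realized latent state of one twin pair (arrays of length 2 per twin)."""

    zygosity: str                 # "MZ" or "DZ"
    A: np.ndarray                 # genetic value per twin (equal within MZ)
    C_effective: np.ndarray       # realized common-environment contribution
    theta: np.ndarray             # latent trait per twin
    sigma2_C: np.ndarray          # moderated common-environment variance
    sigma2_E: np.ndarray          # moderated unique-environment variance


def draw_mz_families(params: GeneratingParams, n: int, rng: np.random.Generator):
    """Vectorized draw of ``n`` MZ families; returns (A, C, theta, s2C, s2E).

    ``A`` and ``C`` have shape (n,) (shared within the pair); ``theta`` is
    (n, 2).  Variance moderation uses the pair-shared genetic value.
    """
    A = rng.normal(0.0, np.sqrt(params.sigma2_A), size=n)
    s2C = np.exp(params.gamma0 + params.gamma1 * A)
    s2E = np.exp(params.beta0 + params.beta1 * A)
    C = rng.normal(0.0, np.sqrt(s2C))
    theta = rng.normal((A + C)[:, None], np.sqrt(s2E)[:, None], size=(n, 2))
    return A, C, theta, s2C, s2E


def draw_dz_families(params: GeneratingParams, n: int, rng: np.random.Generator):
    """Vectorized draw of ``n`` DZ families.

    Returns (A2, C2, theta, s2C, s2E), each of shape (n, 2); each twin's own
    genetic value moderates their environmental variances.
    """
    half = params.sigma2_A / 2.0
    A1 = rng.normal(0.0, np.sqrt(half), size=n)
    A2 = rng.normal(A1[:, None], np.sqrt(half), size=(n, 2))
    C = rng.normal(0.0, 1.0, size=n)
    s2C = np.exp(params.gamma0 + params.gamma1 * A2)
    C2 = C[:, None] * np.sqrt(s2C)
    s2E = np.exp(params.beta0 + params.beta1 * A2)
    theta = rng.normal(A2 + C2, np.sqrt(s2E))
    return A2, C2, theta, s2C, s2E


def draw_mz_family(params: GeneratingParams, rng: np.random.Generator) -> LatentFamily:
    """Draw a single MZ twin pair's latent state."""
    A, C, theta, s2C, s2E = draw_mz_families(params, 1, rng)
    two = np.full(2, A[0])
    return LatentFamily("MZ", two, np.full(2, C[0]), theta[0],
                        np.full(2, s2C[0]), np.full(2, s2E[0]))


def draw_dz_family(params: GeneratingParams, rng: np.random.Generator) -> LatentFamily:
    """Draw a single DZ twin pair's latent state."""
    A2, C2, theta, s2C, s2E = draw_dz_families(params, 1, rng)
    return LatentFamily("DZ", A2[0], C2[0], theta[0], s2C[0], s2E[0])


def sample_gpcm_response(theta, item: ItemParams, rng: np.random.Generator):
    """Draw GPCM categories (0, 1, 2) for trait value(s) ``theta``.

    Scalar ``theta`` gives a scalar int; an array gives an int array.
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    p = gpcm_category_probs(th, item)
    u = rng.random(th.shape)
    cdf = np.cumsum(p, axis=-1)
    cat = (u[..., None] > cdf[..., :2]).sum(axis=-1)
    return cat if np.ndim(theta) else int(cat[0])


def _sample_items(theta: np.ndarray, items, rng: np.random.Generator) -> np.ndarray:
    """Responses (n, k) for all individuals and items in one shot."""
    alphas = np.array([it.alpha for it in items])
    b1s = np.array([it.b1 for it in items])
    b2s = np.array([it.b2 for it in items])
    logp = gpcm_logprob_matrix(theta, alphas, b1s, b2s)   # (n, k, 3)
    cdf = np.cumsum(np.exp(logp), axis=-1)
    u = rng.random(cdf.shape[:2])
    return (u[..., None] > cdf[..., :2]).sum(axis=-1)


def simulate_dataset(params: GeneratingParams) -> pd.DataFrame:
    """Simulate a long-format twin item-response table.

    Returns one row per twin: ``family_id``, ``zygosity``, ``twin`` (1 or 2)
    and ``item_1`` .. ``item_k`` columns (nullable integers; <NA> = missing).
    MZ families come first, then DZ; everything is reproducible from
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    _, _, th_mz, _, _ = draw_mz_families(params, params.n_mz, rng)
    _, _, th_dz, _, _ = draw_dz_families(params, params.n_dz, rng)
    theta = np.concatenate([th_mz.ravel(), th_dz.ravel()])
    y = _sample_items(theta, params.items, rng).astype(float)
    if params.missing_rate > 0:
        mask = rng.random(y.shape) < params.missing_rate
        y[mask] = np.nan

    n_pairs = params.n_mz + params.n_dz
    fam = np.repeat(np.arange(1, n_pairs + 1), 2)
    zyg = np.repeat(["MZ"] * params.n_mz + ["DZ"] * params.n_dz, 2)
    twin = np.tile([1, 2], n_pairs)
    df = pd.DataFrame({"family_id": fam, "zygosity": zyg, "twin": twin})
    for j in range(params.n_items):
        df[f"item_{j + 1}"] = pd.array(y[:, j], dtype="Int64")
    return df


def _item_columns(data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c.startswith("item_")]


def compute_sum_scores(data: pd.DataFrame, reverse_items=(), standardize: bool = False,
                       drop_incomplete: bool = True) -> pd.Series:
    """Per-individual sum scores over the item columns (coded 0, 1, 2).

    Reverse-keyed items (0-based indices into the item columns) are mapped
    x -> 2 - x before summation.  By default individuals with any missing
    scored item are dropped (complete-case scoring); with
    ``drop_incomplete=False`` missing cells simply contribute 0.  With
    ``standardize=True`` scores are rescaled to mean 0 and variance 1 over the
    scored individuals.
    """
    cols = _item_columns(data)
    if not cols:
        raise ValueError("no item columns to score")
    y = data[cols].to_numpy(dtype=float, na_value=np.nan)
    rev = np.asarray(sorted(reverse_items), dtype=int)
    if rev.size:
        y[:, rev] = 2.0 - y[:, rev]
    if drop_incomplete:
        keep = ~np.isnan(y).any(axis=1)
        scores = y[keep].sum(axis=1)
        index = data.index[keep]
    else:
        scores = np.nansum(y, axis=1)
        index = data.index
    if standardize:
        scores = (scores - scores.mean()) / scores.std(ddof=0)
    return pd.Series(scores, index=index, name="score")
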