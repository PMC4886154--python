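"""Bayesian ACE twin model with genotype-environment interaction and GPCM measurement.

The phenotype is a latent trait theta measured by polytomous items through a
generalized partial credit model; theta is decomposed into additive-genetic
(A), common-environment (C) and unique-environment (E) components whose
environmental variances are moderated exp-linearly by the genetic value:

MZ pair i, twin j:
    A_i ~ N(0, sigma2_A);  C_i ~ N(0, exp(gamma0 + gamma1 A_i))
    theta_ij ~ N(A_i + C_i, exp(beta0 + beta1 A_i))

DZ pair i, twin j (genetic correlation 1/2):
    A1_i ~ N(0, sigma2_A/2);  A2_ij ~ N(A1_i, sigma2_A/2);  C_i ~ N(0, 1)
    C2_ij = C_i sqrt(exp(gamma0 + gamma1 A2_ij))
    theta_ij ~ N(A2_ij + C2_ij, exp(beta0 + beta1 A2_ij))

beta1 is the A x E interaction slope, gamma1 the A x C slope.  Measurement and
variance decomposition are estimated *simultaneously* (one-step approach) by a
Metropolis-within-Gibbs sampler: conjugate Gibbs draws where available
(sigma2_A, the C effects, the DZ A1 effects), adaptive random-walk Metropolis
elsewhere, plus family-level translation moves that shift a genetic or
common-environment effect together with the trait values it feeds, which is
essential when the moderated unique-environment variance is small.

Identification: phenotypic mean 0 (all components zero-mean), two free
thresholds per item, and one reference item's discrimination fixed to 1
(default: the third item in input order).

The sum-score variant replaces theta by an observed standardized score and
drops the measurement model; contrasting the two on the same item data
exhibits the skewness artifact in which sum scores distort interaction
estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "Priors",
    "McmcConfig",
    "MODEL_VARIANTS",
    "AceIrtModel",
    "AceSumScoreModel",
    "mcmc_fit_joint",
    "mcmc_fit_sumscore",
    "joint_model_logposterior",
    "hpd_interval",
    "gelman_rubin_psrf",
    "dic",
    "summarize_posterior",
    "compare_models",
]

LOG2PI = math.log(2.0 * math.pi)


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which interaction slopes are free and what the measurement level is."""

    include_axe: bool = True        # beta1 free (True) or fixed at 0
    include_axc: bool = True        # gamma1 free or fixed at 0
    measurement: str = "items"      # "items" or "sumscore"

    @property
    def n_slopes(self) -> int:
        return int(self.include_axe) + int(self.include_axc)

    @property
    def label(self) -> str:
        if self.include_axe and self.include_axc:
            return "ACE model with A x E and A x C"
        if self.include_axe:
            return "ACE model with A x E"
        if self.include_axc:
            return "ACE model with A x C"
        return "No interaction effects (simple ACE model)"


#: The four interaction variants, in increasing order of complexity.
MODEL_VARIANTS: tuple[ModelSpec, ...] = (
    ModelSpec(False, False),
    ModelSpec(True, False),
    ModelSpec(False, True),
    ModelSpec(True, True),
)


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the prior distributions.

    sigma2_A ~ InvGamma(sigma2_a_shape, sigma2_a_scale); the log-variance
    intercepts beta0, gamma0 ~ N(intercept_mean, intercept_var); the slopes
    ~ N(slope_mean, slope_var); thresholds ~ N(0, threshold_var);
    log-discriminations ~ N(0, log_alpha_var).  In variants without an
    interaction the corresponding variance exp(intercept) gets an
    InvGamma(variance_shape, variance_scale) prior instead.  All normal
    hyperparameters are variances, not precisions.
    """

    sigma2_a_shape: float = 1.0
    sigma2_a_scale: float = 1.0
    intercept_mean: float = -1.0
    intercept_var: float = 2.0
    slope_mean: float = 0.0
    slope_var: float = 10.0
    threshold_var: float = 10.0
    log_alpha_var: float = 10.0
    variance_shape: float = 1.0
    variance_scale: float = 1.0

    def __post_init__(self):
        for name in ("sigma2_a_shape", "sigma2_a_scale", "intercept_var",
                     "slope_var", "threshold_var", "log_alpha_var",
                     "variance_shape", "variance_scale"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite number")


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout, iteration counts and adaptation settings."""

    n_chains: int = 6
    burn_in: int = 20_000
    n_kept: int = 20_000            # retained iterations per chain
    thin: int = 1
    seed: int = 0
    adapt_window: int = 50
    target_accept: float = 0.44     # elementwise random-walk target
    target_accept_block: float = 0.234

    def __post_init__(self):
        if min(self.n_chains, self.burn_in, self.n_kept, self.thin) < 1:
            raise ValueError("chain counts and iteration counts must be positive")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcConfig":
        """Six chains, 20,000 burn-in and 20,000 retained iterations each."""
        return cls(seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0) -> "McmcConfig":
        """Reduced preset: 3 chains, 2,000 burn-in, 3,000 kept per chain."""
        return cls(n_chains=3, burn_in=2_000, n_kept=3_000, seed=seed)

    @classmethod
    def sumscore_default(cls, seed: int = 0) -> "McmcConfig":
        """One chain, 10,000 burn-in, 15,000 retained iterations."""
        return cls(n_chains=1, burn_in=10_000, n_kept=15_000, seed=seed)

    @classmethod
    def smoke(cls, seed: int = 0) -> "McmcConfig":
        """Tiny preset for smoke tests."""
        return cls(n_chains=1, burn_in=300, n_kept=400, seed=seed)

    def with_(self, **kw) -> "McmcConfig":
        return replace(self, **kw)


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------

def _prepare_twin_data(data: pd.DataFrame):
    """Validate and order a long-format twin table: MZ block first, then DZ.

    Returns (y, n_mz, n_dz, item_cols) where y is (2*(n_mz+n_dz), k) int with
    -1 marking missing cells, rows ordered family-major, twin-minor.
    """
    df = data
    if "role" in df.columns:
        df = df[df["role"] == "twin"]
    for col in ("family_id", "zygosity", "twin"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    item_cols = [c for c in df.columns if str(c).startswith("item_")]
    zyg = df["zygosity"].astype(str).str.upper()
    bad = ~zyg.isin(["MZ", "DZ"])
    if bad.any():
        raise ValueError(f"unknown zygosity {df['zygosity'][bad].iloc[0]!r} "
                         f"in row {df.index[bad][0]}")
    sizes = df.groupby("family_id").size()
    if (sizes != 2).any():
        fam = sizes.index[sizes != 2][0]
        raise ValueError(f"family {fam!r} has {sizes[fam]} twin rows, expected 2")
    nz = df.groupby("family_id")["zygosity"].nunique()
    if (nz != 1).any():
        raise ValueError(f"family {nz.index[nz != 1][0]!r} mixes zygosity codes")

    order = pd.DataFrame({
        "_z": (zyg != "MZ").astype(int).to_numpy(),
        "_f": df["family_id"].map(
            {f: i for i, f in enumerate(pd.unique(df["family_id"]))}).to_numpy(),
        "_t": df["twin"].to_numpy(),
    }, index=df.index)
    idx = order.sort_values(["_z", "_f", "_t"], kind="stable").index
    df = df.loc[idx]
    n_mz = int((zyg == "MZ").sum()) // 2
    n_dz = len(df) // 2 - n_mz
    if item_cols:
        raw = df[item_cols].to_numpy(dtype=float, na_value=np.nan)
        if np.nanmin(raw, initial=0) < 0 or np.nanmax(raw, initial=0) > 2:
            raise ValueError("item responses must be 0, 1, 2 or missing")
        y = np.where(np.isnan(raw), -1, raw).astype(np.int64)
    else:
        y = np.zeros((len(df), 0), dtype=np.int64)
    return y, n_mz, n_dz, item_cols, df


def _cell_loglik(theta, y, obs, alphas, b1, b2):
    """Exact GPCM log pmf per (person, item) cell; missing cells are 0."""
    t1 = alphas * (theta[:, None] - b1)
    t12 = t1 + alphas * (theta[:, None] - b2)
    m = np.maximum(0.0, np.maximum(t1, t12))
    logz = m + np.log(np.exp(-m) + np.exp(t1 - m) + np.exp(t12 - m))
    w = np.where(y == 1, t1, 0.0)
    w = np.where(y == 2, t12, w)
    return np.where(obs, w - logz, 0.0)


def _norm_logpdf(x, mu, logvar):
    return -0.5 * (LOG2PI + logvar + (x - mu) ** 2 * np.exp(-logvar))


# --------------------------------------------------------------------------
# posterior density (used directly by tests; the sampler mirrors its terms)
# --------------------------------------------------------------------------

def joint_model_logposterior(state: dict, data: pd.DataFrame,
                             spec: ModelSpec | None = None,
                             priors: Priors | None = None,
                             alpha_ref_index: int = 2) -> float:
    """Log posterior density of a full latent + parameter state.

    ``state`` keys: theta (N,), A_mz (n_mz,), C_mz (n_mz,), A1 (n_dz,),
    A2 (n_dz, 2), C_dz (n_dz,), sigma2_A, beta0, beta1, gamma0, gamma1,
    log_alpha (k,), b1 (k,), b2 (k,).  Returns -inf outside the support;
    raises on NaN.
    """
    spec = spec or ModelSpec()
    pr = priors or Priors()
    y, n_mz, n_dz, item_cols, _ = _prepare_twin_data(data)
    th = np.asarray(state["theta"], dtype=float)
    for key, val in state.items():
        if np.any(np.isnan(np.asarray(val, dtype=float))):
            raise ValueError(f"NaN in state component {key!r}")
    s2a = float(state["sigma2_A"])
    if s2a <= 0:
        return -np.inf
    b0, g0 = float(state["beta0"]), float(state["gamma0"])
    b1s = float(state["beta1"]) if spec.include_axe else 0.0
    g1s = float(state["gamma1"]) if spec.include_axc else 0.0

    lp = 0.0
    th_mz = th[:2 * n_mz].reshape(n_mz, 2)
    th_dz = th[2 * n_mz:].reshape(n_dz, 2)
    if n_mz:
        A = np.asarray(state["A_mz"], dtype=float)
        C = np.asarray(state["C_mz"], dtype=float)
        lvC = g0 + g1s * A
        lvE = b0 + b1s * A
        lp += _norm_logpdf(A, 0.0, np.log(s2a)).sum()
        lp += _norm_logpdf(C, 0.0, lvC).sum()
        lp += _norm_logpdf(th_mz, (A + C)[:, None], lvE[:, None]).sum()
    if n_dz:
        A1 = np.asarray(state["A1"], dtype=float)
        A2 = np.asarray(state["A2"], dtype=float)
        Cd = np.asarray(state["C_dz"], dtype=float)
        half = np.log(s2a / 2.0)
        lp += _norm_logpdf(A1, 0.0, half).sum()
        lp += _norm_logpdf(A2, A1[:, None], half).sum()
        lp += _norm_logpdf(Cd, 0.0, 0.0).sum()
        s = np.exp(0.5 * (g0 + g1s * A2))
        lvE = b0 + b1s * A2
        lp += _norm_logpdf(th_dz, A2 + Cd[:, None] * s, lvE).sum()

    if item_cols:
        la = np.asarray(state["log_alpha"], dtype=float)
        bb1 = np.asarray(state["b1"], dtype=float)
        bb2 = np.asarray(state["b2"], dtype=float)
        lp += _cell_loglik(th, y, y >= 0, np.exp(la), bb1, bb2).sum()
        free = np.ones(la.size, dtype=bool)
        free[alpha_ref_index] = False
        lp += -0.5 * (la[free] ** 2 / pr.log_alpha_var).sum()
        lp += -0.5 * ((bb1 ** 2).sum() + (bb2 ** 2).sum()) / pr.threshold_var

    # parameter priors
    lp += (-(pr.sigma2_a_shape + 1.0) * math.log(s2a)
           - pr.sigma2_a_scale / s2a)
    lp += _logvar_intercept_prior(b0, spec.include_axe, pr)
    lp += _logvar_intercept_prior(g0, spec.include_axc, pr)
    if spec.include_axe:
        lp += -0.5 * (b1s - pr.slope_mean) ** 2 / pr.slope_var
    if spec.include_axc:
        lp += -0.5 * (g1s - pr.slope_mean) ** 2 / pr.slope_var
    return float(lp)


def _logvar_intercept_prior(g: float, interaction: bool, pr: Priors) -> float:
    """Log prior of a log-variance intercept (up to a constant).

    With an interaction: Normal(intercept_mean, intercept_var) on the
    log-variance.  Without: InvGamma(variance_shape, variance_scale) on the
    variance exp(g), including the change-of-variables Jacobian.
    """
    if interaction:
        return -0.5 * (g - pr.intercept_mean) ** 2 / pr.intercept_var
    return -pr.variance_shape * g - pr.variance_scale * math.exp(-g)


# --------------------------------------------------------------------------
# single-chain samplers
# --------------------------------------------------------------------------

class _Adapt:
    """Robbins-Monro proposal-scale adaptation, frozen after burn-in."""

    def __init__(self, shape, init, target):
        self.scale = np.full(shape, init, dtype=float)
        self.target = target
        self.acc = np.zeros(shape)

    def step(self, window):
        rate = self.acc / window
        self.scale *= np.exp(np.clip(rate - self.target, -0.5, 0.5))
        np.clip(self.scale, 1e-4, 50.0, out=self.scale)
        self.acc[...] = 0.0


def _run_chain(y, n_mz, n_dz, spec: ModelSpec, pr: Priors, cfg: McmcConfig,
               seed, alpha_ref_index: int, scores=None, init=None):
    """One MCMC chain.  ``scores`` given means sum-score mode (theta observed).

    ``init`` (items mode) carries data-informed starting values computed once
    per fit: trait estimates, item parameters on the reference-item scale and
    moment-based variance components.  Each chain jitters them with its own
    RNG so chains stay dispersed for the PSRF diagnostic.
    """
    rng = np.random.default_rng(seed)
    items_mode = scores is None
    N = 2 * (n_mz + n_dz)
    k = y.shape[1] if items_mode else 0
    i_mz = slice(0, 2 * n_mz)
    i_dz = slice(2 * n_mz, N)

    # ---- initial state ------------------------------------------------
    if items_mode:
        obs = y >= 0
        if init is not None:
            theta = init["theta"] + 0.1 * rng.standard_normal(N)
        else:
            raw = np.where(obs, y.astype(float), np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")   # all-missing rows: nan-mean
                sc = np.nanmean(raw, axis=1)
            sc[np.isnan(sc)] = 1.0
            sd = np.nanstd(sc)
            theta = (sc - np.nanmean(sc)) / (sd if sd > 0 else 1.0)
            theta = theta + 0.1 * rng.standard_normal(N)
    else:
        theta = np.asarray(scores, dtype=float).copy()

    th_mz = theta[i_mz].reshape(n_mz, 2)
    th_dz = theta[i_dz].reshape(n_dz, 2)
    A_mz = 0.5 * th_mz.mean(axis=1)
    C_mz = np.zeros(n_mz)
    A1 = 0.25 * th_dz.mean(axis=1)
    A2 = A1[:, None] + 0.25 * (th_dz - th_dz.mean(axis=1, keepdims=True))
    A2 = np.ascontiguousarray(A2)
    C_dz = np.zeros(n_dz)
    if init is not None:
        s2a = float(init["sigma2_A"] * np.exp(rng.normal(0.0, 0.15)))
        g0 = float(init["gamma0"] + rng.normal(0.0, 0.2))
        b0 = float(init["beta0"] + rng.normal(0.0, 0.2))
    else:
        s2a = float(np.exp(rng.normal(math.log(0.5), 0.3)))
        b0 = float(rng.normal(-1.0, 0.5))
        g0 = float(rng.normal(-1.0, 0.5))
    b1s = float(rng.normal(0.0, 0.2)) if spec.include_axe else 0.0
    g1s = float(rng.normal(0.0, 0.2)) if spec.include_axc else 0.0
    if items_mode:
        if init is not None:
            la = init["log_alpha"] + 0.05 * rng.standard_normal(k)
            la[alpha_ref_index] = 0.0
            bb1 = init["b1"] + 0.05 * rng.standard_normal(k)
            bb2 = init["b2"] + 0.05 * rng.standard_normal(k)
        else:
            la = 0.1 * rng.standard_normal(k)
            la[alpha_ref_index] = 0.0
            bb1 = 0.1 * rng.standard_normal(k)
            bb2 = 0.1 * rng.standard_normal(k)
        alphas = np.exp(la)
        cell = _cell_loglik(theta, y, obs, alphas, bb1, bb2)

    # ---- adaptive proposal scales ------------------------------------
    ad_theta = _Adapt(N, 0.5, cfg.target_accept)
    ad_amz = _Adapt(n_mz, 0.4, cfg.target_accept)
    ad_a2 = _Adapt((n_dz, 2), 0.4, cfg.target_accept)
    ad_shift_amz = _Adapt(n_mz, 0.3, cfg.target_accept)
    ad_shift_cmz = _Adapt(n_mz, 0.3, cfg.target_accept)
    ad_shift_a2 = _Adapt((n_dz, 2), 0.3, cfg.target_accept)
    ad_shift_cdz = _Adapt(n_dz, 0.3, cfg.target_accept)
    ad_swap_mz = _Adapt(n_mz, 0.3, cfg.target_accept)
    ad_swap_dz = _Adapt(n_dz, 0.3, cfg.target_accept)
    ad_item = _Adapt(k if items_mode else 1, 0.08, cfg.target_accept_block)
    ad_glob = {p: _Adapt((), 0.1, cfg.target_accept)
               for p in ("beta0", "beta1", "gamma0", "gamma1")}
    ad_nc = {p: _Adapt((), 0.1, cfg.target_accept_block)
             for p in ("beta0", "beta1", "gamma0", "gamma1")}

    free_item = np.ones(k, dtype=bool) if items_mode else None
    if items_mode:
        free_item[alpha_ref_index] = False

    n_total = cfg.burn_in + cfg.n_kept * cfg.thin
    kept = cfg.n_kept
    out = {p: np.empty(kept) for p in
           ("sigma2_A", "gamma0", "gamma1", "beta0", "beta1", "deviance")}
    if items_mode:
        out["alpha"] = np.empty((kept, k))
        out["b1"] = np.empty((kept, k))
        out["b2"] = np.empty((kept, k))
    theta_sum = np.zeros(N)
    lat_sums = {"A_mz": np.zeros(n_mz), "C_mz": np.zeros(n_mz),
                "A1": np.zeros(n_dz), "A2": np.zeros((n_dz, 2)),
                "C_dz": np.zeros(n_dz)}

    def env_loglik(b0_, b1_, g0_, g1_):
        tot = 0.0
        if n_mz:
            lvC = g0_ + g1_ * A_mz
            lvE = b0_ + b1_ * A_mz
            r2 = ((th_mz - (A_mz + C_mz)[:, None]) ** 2).sum(axis=1)
            tot += -0.5 * (lvC + C_mz ** 2 * np.exp(-lvC)).sum()
            tot += -0.5 * (2.0 * lvE + r2 * np.exp(-lvE)).sum()
        if n_dz:
            lvE = b0_ + b1_ * A2
            s = np.exp(0.5 * (g0_ + g1_ * A2))
            r = th_dz - A2 - C_dz[:, None] * s
            tot += -0.5 * (lvE + r ** 2 * np.exp(-lvE)).sum()
        return tot

    store_i = 0
    for t in range(n_total):
        burning = t < cfg.burn_in

        if items_mode:
            # ---- theta: elementwise random walk -----------------------
            mu = np.empty(N)
            lv = np.empty(N)
            if n_mz:
                mu[i_mz] = np.repeat(A_mz + C_mz, 2)
                lv[i_mz] = np.repeat(b0 + b1s * A_mz, 2)
            if n_dz:
                s_dz = np.exp(0.5 * (g0 + g1s * A2))
                mu[i_dz] = (A2 + C_dz[:, None] * s_dz).ravel()
                lv[i_dz] = (b0 + b1s * A2).ravel()
            prop = theta + ad_theta.scale * rng.standard_normal(N)
            cell_p = _cell_loglik(prop, y, obs, alphas, bb1, bb2)
            e = np.exp(-lv)
            logr = (cell_p.sum(axis=1) - cell.sum(axis=1)
                    - 0.5 * e * ((prop - mu) ** 2 - (theta - mu) ** 2))
            acc = np.log(rng.random(N)) < logr
            theta = np.where(acc, prop, theta)
            cell = np.where(acc[:, None], cell_p, cell)
            ad_theta.acc += acc
            th_mz = theta[i_mz].reshape(n_mz, 2)
            th_dz = theta[i_dz].reshape(n_dz, 2)

            # ---- item parameters: per-item 3-component block RW -------
            step = ad_item.scale[:, None] * rng.standard_normal((k, 3))
            la_p = la + np.where(free_item, step[:, 0], 0.0)
            b1_p = bb1 + step[:, 1]
            b2_p = bb2 + step[:, 2]
            cell_p = _cell_loglik(theta, y, obs, np.exp(la_p), b1_p, b2_p)
            logr = (cell_p.sum(axis=0) - cell.sum(axis=0)
                    - 0.5 * (la_p ** 2 - la ** 2) / pr.log_alpha_var
                    - 0.5 * (b1_p ** 2 - bb1 ** 2) / pr.threshold_var
                    - 0.5 * (b2_p ** 2 - bb2 ** 2) / pr.threshold_var)
            acc = np.log(rng.random(k)) < logr
            la = np.where(acc, la_p, la)
            bb1 = np.where(acc, b1_p, bb1)
            bb2 = np.where(acc, b2_p, bb2)
            alphas = np.exp(la)
            cell = np.where(acc[None, :], cell_p, cell)
            ad_item.acc += acc

        # ---- MZ block -------------------------------------------------
        if n_mz:
            lvC = g0 + g1s * A_mz
            lvE = b0 + b1s * A_mz
            s2C = np.exp(lvC)
            s2E = np.exp(lvE)
            # C_i: conjugate normal
            prec = 1.0 / s2C + 2.0 / s2E
            mean = (th_mz.sum(axis=1) - 2.0 * A_mz) / s2E / prec
            C_mz = mean + rng.standard_normal(n_mz) / np.sqrt(prec)

            # A_i: random walk (moderates both variances)
            def _mz_a_logp(A):
                lvC_ = g0 + g1s * A
                lvE_ = b0 + b1s * A
                r2 = ((th_mz - (A + C_mz)[:, None]) ** 2).sum(axis=1)
                return (-0.5 * A ** 2 / s2a
                        - 0.5 * (lvC_ + C_mz ** 2 * np.exp(-lvC_))
                        - 0.5 * (2.0 * lvE_ + r2 * np.exp(-lvE_)))
            propA = A_mz + ad_amz.scale * rng.standard_normal(n_mz)
            acc = np.log(rng.random(n_mz)) < _mz_a_logp(propA) - _mz_a_logp(A_mz)
            A_mz = np.where(acc, propA, A_mz)
            ad_amz.acc += acc

            # non-centered A move: hold the standardized trait residual and
            # the standardized C fixed, so the Gaussian density terms cancel
            # against the Jacobian and only A-prior and item terms remain
            delta = ad_shift_amz.scale * rng.standard_normal(n_mz)
            A_p = A_mz + delta
            if items_mode:
                lvC = g0 + g1s * A_mz
                lvE = b0 + b1s * A_mz
                lvC_p = g0 + g1s * A_p
                lvE_p = b0 + b1s * A_p
                C_p = C_mz * np.exp(0.5 * (lvC_p - lvC))
                resid = th_mz - (A_mz + C_mz)[:, None]
                th_p = ((A_p + C_p)[:, None]
                        + resid * np.exp(0.5 * (lvE_p - lvE))[:, None]).ravel()
                cell_p = _cell_loglik(th_p, y[i_mz], obs[i_mz],
                                      alphas, bb1, bb2)
                logr = (-0.5 * (A_p ** 2 - A_mz ** 2) / s2a
                        + (cell_p.sum(axis=1) - cell[i_mz].sum(axis=1)
                           ).reshape(n_mz, 2).sum(axis=1))
                acc = np.log(rng.random(n_mz)) < logr
                A_mz = np.where(acc, A_p, A_mz)
                C_mz = np.where(acc, C_p, C_mz)
                acc2 = np.repeat(acc, 2)
                theta[i_mz] = np.where(acc2, th_p, theta[i_mz])
                cell[i_mz] = np.where(acc2[:, None], cell_p, cell[i_mz])
                th_mz = theta[i_mz].reshape(n_mz, 2)
            else:
                # trait observed: plain extra A move at the shift scale
                acc = np.log(rng.random(n_mz)) < _mz_a_logp(A_p) - _mz_a_logp(A_mz)
                A_mz = np.where(acc, A_p, A_mz)
            ad_shift_amz.acc += acc

            if items_mode:
                # translation of C_i with both traits (residuals unchanged)
                delta = ad_shift_cmz.scale * rng.standard_normal(n_mz)
                C_p = C_mz + delta
                lvC = g0 + g1s * A_mz
                th_p = (th_mz + delta[:, None]).ravel()
                cell_p = _cell_loglik(th_p, y[i_mz], obs[i_mz], alphas, bb1, bb2)
                logr = (-0.5 * (C_p ** 2 - C_mz ** 2) * np.exp(-lvC)
                        + (cell_p.sum(axis=1) - cell[i_mz].sum(axis=1)
                           ).reshape(n_mz, 2).sum(axis=1))
                acc = np.log(rng.random(n_mz)) < logr
                C_mz = np.where(acc, C_p, C_mz)
                acc2 = np.repeat(acc, 2)
                theta[i_mz] = np.where(acc2, th_p, theta[i_mz])
                cell[i_mz] = np.where(acc2[:, None], cell_p, cell[i_mz])
                th_mz = theta[i_mz].reshape(n_mz, 2)
                ad_shift_cmz.acc += acc

        # ---- DZ block -------------------------------------------------
        if n_dz:
            half = s2a / 2.0
            # A1: conjugate normal given the pair's A2
            A1 = A2.sum(axis=1) / 3.0 + rng.standard_normal(n_dz) * math.sqrt(half / 3.0)

            # A2: elementwise random walk
            def _dz_a2_logp(A2v):
                lvE_ = b0 + b1s * A2v
                s_ = np.exp(0.5 * (g0 + g1s * A2v))
                r = th_dz - A2v - C_dz[:, None] * s_
                return (-0.5 * (A2v - A1[:, None]) ** 2 / half
                        - 0.5 * (lvE_ + r ** 2 * np.exp(-lvE_)))
            propA = A2 + ad_a2.scale * rng.standard_normal((n_dz, 2))
            acc = np.log(rng.random((n_dz, 2))) < _dz_a2_logp(propA) - _dz_a2_logp(A2)
            A2 = np.where(acc, propA, A2)
            ad_a2.acc += acc

            # non-centered per-twin A2 move: hold the standardized residual
            # fixed; the common effect's contribution C_i s(A2) moves with A2
            delta = ad_shift_a2.scale * rng.standard_normal((n_dz, 2))
            A_p = A2 + delta
            if items_mode:
                lvE = b0 + b1s * A2
                lvE_p = b0 + b1s * A_p
                s_c = np.exp(0.5 * (g0 + g1s * A2))
                s_p = np.exp(0.5 * (g0 + g1s * A_p))
                r_c = th_dz - A2 - C_dz[:, None] * s_c
                th_p = (A_p + C_dz[:, None] * s_p
                        + r_c * np.exp(0.5 * (lvE_p - lvE))).ravel()
                cell_p = _cell_loglik(th_p, y[i_dz], obs[i_dz], alphas, bb1, bb2)
                logr = (-0.5 * ((A_p - A1[:, None]) ** 2
                                - (A2 - A1[:, None]) ** 2) / half
                        + (cell_p.sum(axis=1) - cell[i_dz].sum(axis=1)
                           ).reshape(n_dz, 2))
                acc = np.log(rng.random((n_dz, 2))) < logr
                A2 = np.where(acc, A_p, A2)
                accr = acc.ravel()
                theta[i_dz] = np.where(accr, th_p, theta[i_dz])
                cell[i_dz] = np.where(accr[:, None], cell_p, cell[i_dz])
                th_dz = theta[i_dz].reshape(n_dz, 2)
            else:
                acc = np.log(rng.random((n_dz, 2))) < _dz_a2_logp(A_p) - _dz_a2_logp(A2)
                A2 = np.where(acc, A_p, A2)
            ad_shift_a2.acc += acc

            # C_i: conjugate normal (linear in the scaled effect)
            s_c = np.exp(0.5 * (g0 + g1s * A2))
            e_c = np.exp(b0 + b1s * A2)
            prec = 1.0 + (s_c ** 2 / e_c).sum(axis=1)
            mean = (s_c * (th_dz - A2) / e_c).sum(axis=1) / prec
            C_dz = mean + rng.standard_normal(n_dz) / np.sqrt(prec)

            if items_mode:
                # translation of C_i with both traits (residuals unchanged)
                delta = ad_shift_cdz.scale * rng.standard_normal(n_dz)
                C_p = C_dz + delta
                th_p = (th_dz + delta[:, None] * s_c).ravel()
                cell_p = _cell_loglik(th_p, y[i_dz], obs[i_dz], alphas, bb1, bb2)
                logr = (-0.5 * (C_p ** 2 - C_dz ** 2)
                        + (cell_p.sum(axis=1) - cell[i_dz].sum(axis=1)
                           ).reshape(n_dz, 2).sum(axis=1))
                acc = np.log(rng.random(n_dz)) < logr
                C_dz = np.where(acc, C_p, C_dz)
                acc2 = np.repeat(acc, 2)
                theta[i_dz] = np.where(acc2, th_p, theta[i_dz])
                cell[i_dz] = np.where(acc2[:, None], cell_p, cell[i_dz])
                th_dz = theta[i_dz].reshape(n_dz, 2)
                ad_shift_cdz.acc += acc

        # ---- A <-> C swap moves (trait untouched, no item likelihood) --
        # These traverse the A-versus-C allocation ridge: within a family
        # the trait mean A + C (MZ) or A2 + C2 (DZ, to first order) is
        # preserved, so only priors and moderated variances change.
        if n_mz:
            delta = ad_swap_mz.scale * rng.standard_normal(n_mz)
            A_p = A_mz + delta
            C_p = C_mz - delta
            lvC = g0 + g1s * A_mz
            lvE = b0 + b1s * A_mz
            lvC_p = g0 + g1s * A_p
            lvE_p = b0 + b1s * A_p
            r2 = ((th_mz - (A_mz + C_mz)[:, None]) ** 2).sum(axis=1)
            logr = (-0.5 * (A_p ** 2 - A_mz ** 2) / s2a
                    - 0.5 * (lvC_p - lvC)
                    - 0.5 * (C_p ** 2 * np.exp(-lvC_p) - C_mz ** 2 * np.exp(-lvC))
                    - (lvE_p - lvE)
                    - 0.5 * r2 * (np.exp(-lvE_p) - np.exp(-lvE)))
            acc = np.log(rng.random(n_mz)) < logr
            A_mz = np.where(acc, A_p, A_mz)
            C_mz = np.where(acc, C_p, C_mz)
            ad_swap_mz.acc += acc
        if n_dz:
            half = s2a / 2.0
            delta = ad_swap_dz.scale * rng.standard_normal(n_dz)
            A1_p = A1 + delta
            A2_p = A2 + delta[:, None]
            C_p = C_dz - delta * math.exp(-0.5 * g0)
            lvE = b0 + b1s * A2
            lvE_p = b0 + b1s * A2_p
            s_c = np.exp(0.5 * (g0 + g1s * A2))
            s_p = np.exp(0.5 * (g0 + g1s * A2_p))
            r_c = th_dz - A2 - C_dz[:, None] * s_c
            r_p = th_dz - A2_p - C_p[:, None] * s_p
            logr = (-0.5 * (A1_p ** 2 - A1 ** 2) / half
                    - 0.5 * (C_p ** 2 - C_dz ** 2)
                    - 0.5 * (lvE_p - lvE).sum(axis=1)
                    - 0.5 * (r_p ** 2 * np.exp(-lvE_p)
                             - r_c ** 2 * np.exp(-lvE)).sum(axis=1))
            acc = np.log(rng.random(n_dz)) < logr
            A1 = np.where(acc, A1_p, A1)
            A2 = np.where(acc[:, None], A2_p, A2)
            C_dz = np.where(acc, C_p, C_dz)
            ad_swap_dz.acc += acc

        # ---- sigma2_A: conjugate inverse gamma ------------------------
        ss = (A_mz ** 2).sum() + 2.0 * (A1 ** 2).sum() \
            + 2.0 * ((A2 - A1[:, None]) ** 2).sum()
        shape = pr.sigma2_a_shape + 0.5 * (n_mz + 3 * n_dz)
        s2a = float((pr.sigma2_a_scale + 0.5 * ss) / rng.gamma(shape))

        # ---- environmental-variance parameters ------------------------
        cur_ll = env_loglik(b0, b1s, g0, g1s)
        for name in ("beta0", "beta1", "gamma0", "gamma1"):
            if name == "beta1" and not spec.include_axe:
                continue
            if name == "gamma1" and not spec.include_axc:
                continue
            ad = ad_glob[name]
            step = float(ad.scale) * float(rng.standard_normal())
            nb0, nb1, ng0, ng1 = b0, b1s, g0, g1s
            if name == "beta0":
                nb0 += step
                dprior = (_logvar_intercept_prior(nb0, spec.include_axe, pr)
                          - _logvar_intercept_prior(b0, spec.include_axe, pr))
            elif name == "beta1":
                nb1 += step
                dprior = -0.5 * ((nb1 - pr.slope_mean) ** 2
                                 - (b1s - pr.slope_mean) ** 2) / pr.slope_var
            elif name == "gamma0":
                ng0 += step
                dprior = (_logvar_intercept_prior(ng0, spec.include_axc, pr)
                          - _logvar_intercept_prior(g0, spec.include_axc, pr))
            else:
                ng1 += step
                dprior = -0.5 * ((ng1 - pr.slope_mean) ** 2
                                 - (g1s - pr.slope_mean) ** 2) / pr.slope_var
            new_ll = env_loglik(nb0, nb1, ng0, ng1)
            if math.log(rng.random()) < new_ll - cur_ll + dprior:
                b0, b1s, g0, g1s = nb0, nb1, ng0, ng1
                cur_ll = new_ll
                ad.acc += 1

        # ---- non-centered global variance-parameter moves --------------
        # Propose a new intercept/slope and transform every C effect and
        # trait value so standardized effects and residuals are preserved;
        # Gaussian density terms cancel against the Jacobian, leaving the
        # prior and the item likelihood to decide acceptance.
        if items_mode:
            for name in ("beta0", "beta1", "gamma0", "gamma1"):
                if name == "beta1" and not spec.include_axe:
                    continue
                if name == "gamma1" and not spec.include_axc:
                    continue
                ad = ad_nc[name]
                step = float(ad.scale) * float(rng.standard_normal())
                nb0, nb1, ng0, ng1 = b0, b1s, g0, g1s
                if name == "beta0":
                    nb0 += step
                    dprior = (_logvar_intercept_prior(nb0, spec.include_axe, pr)
                              - _logvar_intercept_prior(b0, spec.include_axe, pr))
                elif name == "beta1":
                    nb1 += step
                    dprior = -0.5 * ((nb1 - pr.slope_mean) ** 2
                                     - (b1s - pr.slope_mean) ** 2) / pr.slope_var
                elif name == "gamma0":
                    ng0 += step
                    dprior = (_logvar_intercept_prior(ng0, spec.include_axc, pr)
                              - _logvar_intercept_prior(g0, spec.include_axc, pr))
                else:
                    ng1 += step
                    dprior = -0.5 * ((ng1 - pr.slope_mean) ** 2
                                     - (g1s - pr.slope_mean) ** 2) / pr.slope_var
                th_p = np.empty(N)
                if n_mz:
                    lvC = g0 + g1s * A_mz
                    lvC_p = ng0 + ng1 * A_mz
                    C_p_mz = C_mz * np.exp(0.5 * (lvC_p - lvC))
                    fac = np.exp(0.5 * ((nb0 + nb1 * A_mz)
                                        - (b0 + b1s * A_mz)))
                    resid = th_mz - (A_mz + C_mz)[:, None]
                    th_p[i_mz] = ((A_mz + C_p_mz)[:, None]
                                  + resid * fac[:, None]).ravel()
                if n_dz:
                    s_c = np.exp(0.5 * (g0 + g1s * A2))
                    s_p = np.exp(0.5 * (ng0 + ng1 * A2))
                    fac = np.exp(0.5 * ((nb0 + nb1 * A2) - (b0 + b1s * A2)))
                    resid = th_dz - A2 - C_dz[:, None] * s_c
                    th_p[i_dz] = (A2 + C_dz[:, None] * s_p
                                  + resid * fac).ravel()
                cell_p = _cell_loglik(th_p, y, obs, alphas, bb1, bb2)
                if math.log(rng.random()) < cell_p.sum() - cell.sum() + dprior:
                    b0, b1s, g0, g1s = nb0, nb1, ng0, ng1
                    theta = th_p
                    cell = cell_p
                    if n_mz:
                        C_mz = C_p_mz
                    th_mz = theta[i_mz].reshape(n_mz, 2)
                    th_dz = theta[i_dz].reshape(n_dz, 2)
                    ad.acc += 1

        # ---- adaptation / storage ------------------------------------
        if burning and (t + 1) % cfg.adapt_window == 0:
            for ad in (ad_theta, ad_amz, ad_a2, ad_shift_amz, ad_shift_cmz,
                       ad_shift_a2, ad_shift_cdz, ad_swap_mz, ad_swap_dz,
                       ad_item, *ad_glob.values(), *ad_nc.values()):
                ad.step(cfg.adapt_window)

        if not burning and (t - cfg.burn_in) % cfg.thin == 0:
            if items_mode:
                devi = -2.0 * cell.sum()
            else:
                mu = np.empty(N)
                lv = np.empty(N)
                if n_mz:
                    mu[i_mz] = np.repeat(A_mz + C_mz, 2)
                    lv[i_mz] = np.repeat(b0 + b1s * A_mz, 2)
                if n_dz:
                    s_dz = np.exp(0.5 * (g0 + g1s * A2))
                    mu[i_dz] = (A2 + C_dz[:, None] * s_dz).ravel()
                    lv[i_dz] = (b0 + b1s * A2).ravel()
                devi = -2.0 * _norm_logpdf(theta, mu, lv).sum()
            out["sigma2_A"][store_i] = s2a
            out["beta0"][store_i] = b0
            out["beta1"][store_i] = b1s
            out["gamma0"][store_i] = g0
            out["gamma1"][store_i] = g1s
            out["deviance"][store_i] = devi
            if items_mode:
                out["alpha"][store_i] = alphas
                out["b1"][store_i] = bb1
                out["b2"][store_i] = bb2
            theta_sum += theta
            lat_sums["A_mz"] += A_mz
            lat_sums["C_mz"] += C_mz
            lat_sums["A1"] += A1
            lat_sums["A2"] += A2
            lat_sums["C_dz"] += C_dz
            store_i += 1

    out["theta_sum"] = theta_sum
    out["lat_sums"] = lat_sums
    return out


# --------------------------------------------------------------------------
# posterior utilities
# --------------------------------------------------------------------------

def hpd_interval(samples, mass: float = 0.95):
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally short windows resolve to the lowest start.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    if not (0 < mass <= 1):
        raise ValueError("mass must be in (0, 1]")
    m = min(max(int(math.ceil(mass * n)), 1), n)
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))          # first minimum = lowest start
    return float(x[i]), float(x[i + m - 1])


def gelman_rubin_psrf(chains) -> float:
    """Potential scale reduction factor over chains of equal length.

    PSRF = sqrt(((n-1)/n W + B/n) / W) with W the mean within-chain variance
    and B/n the between-chain variance of the chain means.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = c.shape[1]
    w = c.var(axis=1, ddof=1).mean()
    if w == 0:
        raise ValueError("zero within-chain variance")
    b_over_n = c.mean(axis=1).var(ddof=1)
    return float(math.sqrt(((n - 1) / n * w + b_over_n) / w))


def dic(deviances, deviance_at_means: float):
    """(DIC, pD) from stored per-iteration deviances and the plug-in deviance.

    pD = mean(D) - D(posterior means of the focus parameters); DIC = mean(D) + pD.
    The deviance focus here is the observed nodes given their parents.
    """
    d = np.asarray(deviances, dtype=float).ravel()
    if d.size < 10:
        raise ValueError("need at least 10 retained deviance evaluations")
    dbar = float(d.mean())
    pd_ = dbar - float(deviance_at_means)
    return dbar + pd_, pd_


def summarize_posterior(chains: dict, spec: ModelSpec | None = None,
                        mass: float = 0.95) -> pd.DataFrame:
    """Per-parameter mean, SD, HPD bounds, PSRF and significance flags.

    ``chains`` maps parameter name -> (n_chains, n_kept) array.  Derived rows
    ``exp_gamma0``, ``exp_beta0`` and the per-draw heritability
    h2 = sigma2_A / (sigma2_A + exp(gamma0) + exp(beta0)) are added when their
    ingredients are present.  A parameter is flagged significant when its HPD
    excludes 0.
    """
    spec = spec or ModelSpec()
    ch = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in chains.items()
          if np.asarray(v).ndim <= 2}
    if {"sigma2_A", "gamma0", "beta0"} <= ch.keys():
        ch["exp_gamma0"] = np.exp(ch["gamma0"])
        ch["exp_beta0"] = np.exp(ch["beta0"])
        ch["h2"] = ch["sigma2_A"] / (ch["sigma2_A"] + ch["exp_gamma0"]
                                     + ch["exp_beta0"])
    rows = []
    for name, c in ch.items():
        flat = c.ravel()
        lo, hi = hpd_interval(flat, mass)
        if c.shape[0] >= 2 and flat.std() > 0:
            try:
                psrf = gelman_rubin_psrf(c)
            except ValueError:
                psrf = np.nan
        else:
            psrf = np.nan
        rows.append({"parameter": name, "mean": flat.mean(),
                     "sd": flat.std(ddof=1) if flat.size > 1 else 0.0,
                     "hpd_low": lo, "hpd_high": hi, "psrf": psrf,
                     "significant": bool(lo > 0 or hi < 0)})
    return pd.DataFrame(rows).set_index("parameter")


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

class _AceBase(BaseEstimator):
    def __init__(self, include_axe=True, include_axc=True, priors=None,
                 config=None, alpha_ref_index=2, hpd_mass=0.95,
                 psrf_threshold=1.1):
        self.include_axe = include_axe
        self.include_axc = include_axc
        self.priors = priors
        self.config = config
        self.alpha_ref_index = alpha_ref_index
        self.hpd_mass = hpd_mass
        self.psrf_threshold = psrf_threshold

    def _spec(self, measurement):
        return ModelSpec(self.include_axe, self.include_axc, measurement)

    def _collect(self, results, keys, k_items=0):
        chains = {}
        for p in keys:
            chains[p] = np.stack([r[p] for r in results])
        for j in range(k_items):
            for p in ("alpha", "b1", "b2"):
                chains[f"{p}_{j + 1}"] = np.stack([r[p][:, j] for r in results])
        return chains

    def _finish(self, spec, chains, dev_at_means):
        summary = summarize_posterior(chains, spec, self.hpd_mass)
        self.chains_ = chains
        self.summary_ = summary
        self.dic_, self.pd_ = dic(chains["deviance"], dev_at_means)
        self.deviance_at_means_ = dev_at_means
        core = [p for p in ("sigma2_A", "exp_gamma0", "exp_beta0", "beta1",
                            "gamma1", "h2") if p in summary.index]
        bad = summary.loc[core, "psrf"].dropna()
        bad = bad[bad > self.psrf_threshold]
        self.psrf_warnings_ = list(bad.index)
        if len(bad):
            warnings.warn("PSRF above threshold for: "
                          + ", ".join(f"{p}={v:.3f}" for p, v in bad.items()))
        return self

    def hpd(self, parameter: str):
        return hpd_interval(self.chains_[parameter].ravel(), self.hpd_mass)


def _informed_init(yy, n_mz, n_dz, alpha_ref_index):
    """Data-informed starting values: MML item fit, EAP traits rescaled to
    the fixed-discrimination convention, moment-based A/C/E split."""
    from .irt import GeneralizedPartialCredit, rescale_item_params

    X = np.where(yy >= 0, yy.astype(float), np.nan)
    try:
        mml = GeneralizedPartialCredit("GPCM", n_quadrature=31, max_iter=200,
                                       tol=1e-4).fit(X)
    except Exception:
        return None
    items, trait_var = rescale_item_params(mml.items_, alpha_ref_index)
    a_ref = float(mml.alphas_[alpha_ref_index])
    theta = mml.eap_scores(X) * a_ref
    th_mz = theta[:2 * n_mz].reshape(n_mz, 2)
    th_dz = theta[2 * n_mz:].reshape(n_dz, 2)
    var = max(float(theta.var()), 1e-3)
    cov_mz = (float(np.cov(th_mz[:, 0], th_mz[:, 1])[0, 1]) if n_mz > 1
              else 0.5 * var)
    cov_dz = (float(np.cov(th_dz[:, 0], th_dz[:, 1])[0, 1]) if n_dz > 1
              else 0.25 * var)
    s2a = float(np.clip(2.0 * (cov_mz - cov_dz), 0.05 * var, trait_var))
    s2c = float(np.clip(2.0 * cov_dz - cov_mz, 0.02 * var, trait_var))
    # EAP scores are shrunken, so take E as the remainder of the implied
    # total trait variance on the reference-item scale
    s2e = float(np.clip(trait_var - s2a - s2c, 0.02 * var, None))
    return {"theta": theta,
            "log_alpha": np.log([it.alpha for it in items]),
            "b1": np.array([it.b1 for it in items]),
            "b2": np.array([it.b2 for it in items]),
            "sigma2_A": s2a, "gamma0": math.log(s2c), "beta0": math.log(s2e)}


class AceIrtModel(_AceBase):
    """Joint Bayesian GPCM + ACE model with optional A x E / A x C moderation.

    Fitted attributes: ``chains_`` (parameter -> (n_chains, n_kept) array),
    ``summary_`` (posterior mean/SD/HPD/PSRF table including exp(gamma0),
    exp(beta0) and per-draw heritability), ``dic_``, ``pd_``, ``theta_mean_``,
    ``psrf_warnings_``.
    """

    def fit(self, X, y=None):
        spec = self._spec("items")
        pr = self.priors or Priors()
        cfg = self.config or McmcConfig()
        yy, n_mz, n_dz, item_cols, ordered = _prepare_twin_data(X)
        if not item_cols:
            raise ValueError("no item_* columns in the data")
        if n_mz + n_dz < 2:
            raise ValueError("need at least 2 twin families")
        k = yy.shape[1]
        if not (0 <= self.alpha_ref_index < k):
            raise ValueError("alpha_ref_index out of range")
        init = _informed_init(yy, n_mz, n_dz, self.alpha_ref_index)
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        results = [_run_chain(yy, n_mz, n_dz, spec, pr, cfg, s,
                              self.alpha_ref_index, init=init) for s in seeds]
        chains = self._collect(results, ("sigma2_A", "gamma0", "gamma1",
                                         "beta0", "beta1", "deviance"), k)
        n_draws = cfg.n_kept * cfg.n_chains
        theta_mean = sum(r["theta_sum"] for r in results) / n_draws
        alpha_mean = np.stack([chains[f"alpha_{j+1}"].ravel() for j in range(k)]).mean(axis=1)
        b1_mean = np.stack([chains[f"b1_{j+1}"].ravel() for j in range(k)]).mean(axis=1)
        b2_mean = np.stack([chains[f"b2_{j+1}"].ravel() for j in range(k)]).mean(axis=1)
        dev_hat = -2.0 * _cell_loglik(theta_mean, yy, yy >= 0, alpha_mean,
                                      b1_mean, b2_mean).sum()
        self.theta_mean_ = theta_mean
        self.item_means_ = pd.DataFrame({"alpha": alpha_mean, "b1": b1_mean,
                                         "b2": b2_mean},
                                        index=item_cols)
        self.n_families_ = (n_mz, n_dz)
        return self._finish(spec, chains, dev_hat)


class AceSumScoreModel(_AceBase):
    """Bayesian ACE model on observed standardized sum scores (no IRT part)."""

    def fit(self, X, y=None):
        spec = self._spec("sumscore")
        pr = self.priors or Priors()
        cfg = self.config or McmcConfig.sumscore_default()
        if "score" not in X.columns:
            raise ValueError("expected a 'score' column")
        _, n_mz, n_dz, _, ordered = _prepare_twin_data(X)
        scores = ordered["score"].to_numpy(dtype=float)
        if np.isnan(scores).any():
            raise ValueError("scores must be complete")
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        yy = np.zeros((scores.size, 0), dtype=np.int64)
        results = [_run_chain(yy, n_mz, n_dz, spec, pr, cfg, s,
                              self.alpha_ref_index, scores=scores)
                   for s in seeds]
        chains = self._collect(results, ("sigma2_A", "gamma0", "gamma1",
                                         "beta0", "beta1", "deviance"))
        n_draws = cfg.n_kept * cfg.n_chains
        lat = {kk: sum(r["lat_sums"][kk] for r in results) / n_draws
               for kk in results[0]["lat_sums"]}
        means = {p: chains[p].mean() for p in ("sigma2_A", "gamma0", "gamma1",
                                               "beta0", "beta1")}
        N = scores.size
        mu = np.empty(N)
        lv = np.empty(N)
        if n_mz:
            mu[:2 * n_mz] = np.repeat(lat["A_mz"] + lat["C_mz"], 2)
            lv[:2 * n_mz] = np.repeat(means["beta0"]
                                      + means["beta1"] * lat["A_mz"], 2)
        if n_dz:
            s = np.exp(0.5 * (means["gamma0"] + means["gamma1"] * lat["A2"]))
            mu[2 * n_mz:] = (lat["A2"] + lat["C_dz"][:, None] * s).ravel()
            lv[2 * n_mz:] = (means["beta0"] + means["beta1"] * lat["A2"]).ravel()
        dev_hat = -2.0 * _norm_logpdf(scores, mu, lv).sum()
        self.n_families_ = (n_mz, n_dz)
        return self._finish(spec, chains, dev_hat)


def mcmc_fit_joint(data, spec: ModelSpec | None = None,
                   priors: Priors | None = None,
                   config: McmcConfig | None = None,
                   alpha_ref_index: int = 2) -> AceIrtModel:
    """Fit the joint IRT + ACE model; thin estimator wrapper."""
    spec = spec or ModelSpec()
    return AceIrtModel(spec.include_axe, spec.include_axc, priors, config,
                       alpha_ref_index).fit(data)


def mcmc_fit_sumscore(scores, spec: ModelSpec | None = None,
                      priors: Priors | None = None,
                      config: McmcConfig | None = None) -> AceSumScoreModel:
    """Fit the biometric model on observed sum scores; thin wrapper."""
    spec = spec or ModelSpec()
    return AceSumScoreModel(spec.include_axe, spec.include_axc, priors,
                            config or McmcConfig.sumscore_default()).fit(scores)


def compare_models(data, priors: Priors | None = None,
                   config: McmcConfig | None = None,
                   alpha_ref_index: int = 2):
    """Fit the four interaction variants and rank them by DIC.

    Returns ``(table, best_label)``: a DataFrame with one row per variant
    (model label, DIC, pD, error message if the fit failed) and the label of
    the DIC-minimizing variant; DIC ties resolve to the model with fewer free
    interaction slopes.  Per-variant failures are recorded and the remaining
    variants still run.
    """
    rows = []
    for spec in MODEL_VARIANTS:
        try:
            fit = mcmc_fit_joint(data, spec, priors, config, alpha_ref_index)
            rows.append({"model": spec.label, "dic": fit.dic_, "pd": fit.pd_,
                         "n_slopes": spec.n_slopes, "error": ""})
        except Exception as exc:       # propagate per row, continue others
            rows.append({"model": spec.label, "dic": np.nan, "pd": np.nan,
                         "n_slopes": spec.n_slopes, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["dic"])
    if ok.empty:
        raise RuntimeError("all model fits failed: "
                           + "; ".join(table["error"]))
    best = ok.sort_values(["dic", "n_slopes"], kind="stable").iloc[0]["model"]
    return table.drop(columns="n_slopes"), best
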