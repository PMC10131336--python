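"""Kernel mixed models for genomic prediction.

Two model families over a relationship kernel ``G``:

* ``fit_gblup`` — the linear mixed model ``Y_i = mu + g_i + eps_i`` with
  ``g ~ N(0, sigma_g^2 G)``, fit either by Gibbs sampling (masked phenotypes
  imputed each sweep) or deterministically by REML + conditional BLUP.
* ``fit_tgblup`` — the probit threshold model ``P(Y_bi = 1 | g_i) =
  Phi(beta0 + g_i)`` with a latent liability ``l_i = beta0 + g_i + eps_i``,
  unit residual variance and a flat prior on ``beta0``, fit by Gibbs sampling
  with truncated-normal data augmentation.

Both samplers update the genomic effect in the eigenbasis of ``G``: one
O(n^3) decomposition, then O(n) per-coordinate conditionals plus two
matrix-vector products per sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, special

from .io_kinship import KinshipMatrix

_EIG_TOL = 1e-10
_PSD_JITTER = 1e-6


class ModelError(ValueError):
    """Raised for unusable model inputs (degenerate labels, bad kernel, ...)."""


@dataclass
class McmcConfig:
    """Gibbs sampler settings and scaled-inverse-chi-square prior hyperparameters."""

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0
    df_e: float = 5.0
    df_g: float = 5.0
    scale_e: float = None  # default: matched to 0.5 * var(y)
    scale_g: float = None

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ModelError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ModelError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class GBLUPFit:
    mu: float
    g_hat: np.ndarray
    sigma2_e: float
    sigma2_g: float
    train_ids: list
    all_ids: list
    mode: str
    mcmc_meta: dict = field(default_factory=dict)
    g_sd: np.ndarray = None
    gdiag_mean: float = 1.0

    @property
    def heritability(self) -> float:
        """Genomic variance share on the observed scale.

        The genomic variance contributed to a phenotype is
        ``sigma2_g * mean(diag(G))``, so the estimate is invariant to the
        overall scaling of the kernel.
        """
        vg = self.sigma2_g * self.gdiag_mean
        tot = vg + self.sigma2_e
        return vg / tot if tot > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "model": "gblup",
            "mode": self.mode,
            "mu": self.mu,
            "sigma2_e": self.sigma2_e,
            "sigma2_g": self.sigma2_g,
            "train_ids": list(self.train_ids),
            "lines": {
                l: {"g_hat": float(g)} for l, g in zip(self.all_ids, self.g_hat)
            },
            "mcmc_meta": self.mcmc_meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class TGBLUPFit:
    beta0: float
    g_hat: np.ndarray
    sigma2_g: float
    train_ids: list
    all_ids: list
    proba_mode: str = "posterior_mean_of_phi"
    mcmc_meta: dict = field(default_factory=dict)
    proba_mean_phi: np.ndarray = None  # mean over samples of Phi(beta0 + g)
    proba_phi_mean: np.ndarray = None  # Phi(posterior mean of beta0 + g)

    def to_dict(self) -> dict:
        return {
            "model": "tgblup",
            "beta0": self.beta0,
            "sigma2_g": self.sigma2_g,
            "proba_mode": self.proba_mode,
            "train_ids": list(self.train_ids),
            "lines": {
                l: {"g_hat": float(g), "proba": float(p)}
                for l, g, p in zip(self.all_ids, self.g_hat, self.proba_mean_phi)
            },
            "mcmc_meta": self.mcmc_meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# shared helpers


def _checked_eigh(K: KinshipMatrix):
    """Eigendecompose G; jitter mildly negative spectra, reject the rest."""
    d, U = np.linalg.eigh(K.G)
    dmax = max(float(d[-1]), 1.0)
    if d[0] < -1e-8 * dmax:
        if d[0] < -1e-4 * dmax:
            raise ModelError(
                f"kinship matrix is not PSD (min eigenvalue {d[0]:.3g})"
            )
        d = d + (_PSD_JITTER * dmax - d[0])
    d = np.clip(d, 0.0, None)
    return d, U


def _scaled_inv_chi2(rng, df: float, scale_times_df: float, n: float, ss: float):
    """Draw from the scaled-inverse-chi-square full conditional."""
    return (ss + scale_times_df) / rng.chisquare(df + n)


def _default_scale(df: float, target_var: float) -> float:
    # prior mode df*S/(df+2) matched to the target variance share
    return target_var * (df + 2.0) / df


def _sample_trunc_normal(rng, mean, lower_positive):
    """Vector draw of N(mean, 1) truncated to l > 0 (where lower_positive)
    or l < 0 (elsewhere), by inverse-CDF."""
    u = rng.uniform(size=mean.shape)
    f0 = special.ndtr(-mean)  # P(l < 0)
    q = np.where(lower_positive, f0 + u * (1.0 - f0), u * f0)
    q = np.clip(q, 1e-16, 1.0 - 1e-16)
    return mean + special.ndtri(q)


# ---------------------------------------------------------------------------
# GBLUP (regression)


def fit_gblup(
    y_values: np.ndarray,
    K: KinshipMatrix,
    cfg: McmcConfig = None,
    mode: str = "gibbs",
    lambda_fixed: float = None,
    fixed_variances: tuple = None,
    min_observed: int = 20,
) -> GBLUPFit:
    """Fit the GBLUP regression model; NaN entries of ``y_values`` are
    treated as masked test lines and predicted by the joint model.

    Parameters
    ----------
    y_values : array aligned with ``K.line_ids``; NaN marks masked lines.
    mode : "gibbs" (Bayesian, posterior means) or "blup_deterministic"
        (1-D profile REML over lambda = sigma2_e/sigma2_g, then the
        conditional-BLUP solve).
    lambda_fixed : skip REML and use this variance ratio (deterministic mode).
    fixed_variances : optional (sigma2_g, sigma2_e) to hold fixed in the
        Gibbs sampler (for convergence diagnostics).
    """
    y = np.asarray(y_values, dtype=float)
    if y.shape[0] != len(K.line_ids):
        raise ModelError("phenotype vector does not match kinship ids")
    obs = ~np.isnan(y)
    n_obs = int(obs.sum())
    if n_obs < min_observed:
        raise ModelError(f"only {n_obs} observed phenotypes (< {min_observed})")
    all_ids = list(K.line_ids)
    train_ids = [l for l, o in zip(all_ids, obs) if o]

    if mode == "blup_deterministic":
        return _fit_gblup_reml(y, obs, K, all_ids, train_ids, lambda_fixed)
    if mode != "gibbs":
        raise ModelError(f"unknown fit mode {mode!r}")
    cfg = cfg or McmcConfig()
    return _fit_gblup_gibbs(y, obs, K, all_ids, train_ids, cfg, fixed_variances)


def _fit_gblup_reml(y, obs, K, all_ids, train_ids, lambda_fixed):
    y_obs = y[obs]
    n = y_obs.shape[0]
    if np.var(y_obs) <= 1e-12 * (1.0 + np.mean(y_obs) ** 2):
        return GBLUPFit(
            mu=float(np.mean(y_obs)), g_hat=np.zeros(len(all_ids)),
            sigma2_e=1e-12, sigma2_g=0.0,
            train_ids=train_ids, all_ids=all_ids, mode="blup_deterministic",
        )
    G_oo = K.G[np.ix_(obs, obs)]
    d, U = _checked_eigh(KinshipMatrix(train_ids, G_oo))
    yt = U.T @ y_obs
    xt = U.T @ np.ones(n)

    def profile(log_lam):
        lam = np.exp(log_lam)
        w = 1.0 / (d + lam)
        xx = np.sum(w * xt * xt)
        mu = np.sum(w * xt * yt) / xx
        r = yt - mu * xt
        s2g = max(np.sum(w * r * r) / (n - 1), 1e-300)
        # REML log-likelihood up to an additive constant
        ll = -0.5 * (
            (n - 1) * np.log(s2g) + np.sum(np.log(d + lam)) + np.log(xx)
            + (n - 1)
        )
        return ll, mu, s2g

    if lambda_fixed is not None:
        lam = float(lambda_fixed)
        _, mu, s2g = profile(np.log(lam))
    else:
        res = optimize.minimize_scalar(
            lambda t: -profile(t)[0],
            bounds=(np.log(1e-6), np.log(1e6)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        _, mu, s2g = profile(res.x)
    s2e = lam * s2g
    # conditional BLUP for every line: g = G[:,obs] (G_oo + lam I)^-1 (y - mu)
    w = 1.0 / (d + lam)
    rhs = U @ (w * (U.T @ (y_obs - mu)))
    g_all = K.G[:, obs] @ rhs
    return GBLUPFit(
        mu=float(mu), g_hat=g_all, sigma2_e=float(s2e), sigma2_g=float(s2g),
        train_ids=train_ids, all_ids=all_ids, mode="blup_deterministic",
        mcmc_meta={"lambda": lam, "reml": lambda_fixed is None},
        gdiag_mean=float(np.mean(np.diag(K.G))),
    )


def _fit_gblup_gibbs(y, obs, K, all_ids, train_ids, cfg, fixed_variances):
    rng = np.random.default_rng(cfg.seed)
    n = len(all_ids)
    d, U = _checked_eigh(K)
    pos = d > _EIG_TOL * max(d[-1], 1.0)
    n_pos = int(pos.sum())

    y_obs_var = float(np.var(y[obs]))
    vy = y_obs_var if y_obs_var > 0 else 1.0
    S_e = cfg.scale_e if cfg.scale_e is not None else _default_scale(cfg.df_e, 0.5 * vy)
    S_g = cfg.scale_g if cfg.scale_g is not None else _default_scale(cfg.df_g, 0.5 * vy)

    mu = float(np.mean(y[obs]))
    alpha = np.zeros(n)
    if fixed_variances is not None:
        s2g, s2e = float(fixed_variances[0]), float(fixed_variances[1])
    else:
        s2g = s2e = 0.5 * vy
    yw = y.copy()
    yw[~obs] = mu

    acc = {"mu": 0.0, "s2e": 0.0, "s2g": 0.0}
    g_sum = np.zeros(n)
    g_sumsq = np.zeros(n)
    retained = 0

    for it in range(cfg.n_iter):
        g = U @ alpha
        # impute masked phenotypes from their conditional normal
        n_miss = n - len(train_ids)
        if n_miss:
            yw[~obs] = mu + g[~obs] + np.sqrt(s2e) * rng.standard_normal(n_miss)
        # intercept
        mu = float(np.mean(yw - g)) + np.sqrt(s2e / n) * rng.standard_normal()
        # genomic effect in the eigenbasis
        rt = U.T @ (yw - mu)
        prec = np.where(pos, 1.0 / s2e + 1.0 / (s2g * np.maximum(d, _EIG_TOL)), np.inf)
        mean_a = np.where(pos, (rt / s2e) / prec, 0.0)
        sd_a = np.where(pos, np.sqrt(1.0 / prec), 0.0)
        alpha = mean_a + sd_a * rng.standard_normal(n)
        g = U @ alpha
        if fixed_variances is None:
            sse = float(np.sum((yw - mu - g) ** 2))
            s2e = _scaled_inv_chi2(rng, cfg.df_e, cfg.df_e * S_e, n, sse)
            ssg = float(np.sum(alpha[pos] ** 2 / d[pos]))
            s2g = _scaled_inv_chi2(rng, cfg.df_g, cfg.df_g * S_g, n_pos, ssg)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            retained += 1
            acc["mu"] += mu
            acc["s2e"] += s2e
            acc["s2g"] += s2g
            g_sum += g
            g_sumsq += g * g

    g_hat = g_sum / retained
    g_var = np.maximum(g_sumsq / retained - g_hat**2, 0.0)
    return GBLUPFit(
        mu=acc["mu"] / retained,
        g_hat=g_hat,
        sigma2_e=acc["s2e"] / retained,
        sigma2_g=acc["s2g"] / retained,
        train_ids=train_ids,
        all_ids=all_ids,
        mode="gibbs",
        mcmc_meta={**asdict(cfg), "n_retained": retained,
                   "fixed_variances": fixed_variances is not None},
        g_sd=np.sqrt(g_var),
        gdiag_mean=float(np.mean(np.diag(K.G))),
    )


def predict_gblup(fit: GBLUPFit, ids) -> np.ndarray:
    """Continuous predictions ``mu + g_hat`` for the requested line ids."""
    index = {l: k for k, l in enumerate(fit.all_ids)}
    try:
        sel = [index[i] for i in ids]
    except KeyError as exc:
        raise ModelError(f"unknown line id {exc.args[0]!r}") from None
    return fit.mu + fit.g_hat[sel]


# ---------------------------------------------------------------------------
# TGBLUP (probit threshold classification)


def fit_tgblup(
    yb_values: np.ndarray,
    K: KinshipMatrix,
    cfg: McmcConfig = None,
) -> TGBLUPFit:
    """Fit the probit threshold model by truncated-normal data augmentation.

    ``yb_values`` is aligned with ``K.line_ids``; entries must be 0, 1 or NaN
    (masked test lines).  Residual liability variance is fixed at 1 and the
    intercept carries a flat prior.
    """
    cfg = cfg or McmcConfig()
    yb = np.asarray(yb_values, dtype=float)
    if yb.shape[0] != len(K.line_ids):
        raise ModelError("label vector does not match kinship ids")
    obs = ~np.isnan(yb)
    if not np.isin(yb[obs], (0.0, 1.0)).all():
        raise ModelError("labels must be 0/1/NaN")
    labels = yb[obs]
    if labels.min() == labels.max():
        raise ModelError(
            "degenerate binarization: only one class among observed labels — "
            "raise tau or check the threshold"
        )
    all_ids = list(K.line_ids)
    train_ids = [l for l, o in zip(all_ids, obs) if o]
    n = len(all_ids)

    rng = np.random.default_rng(cfg.seed)
    d, U = _checked_eigh(K)
    pos = d > _EIG_TOL * max(d[-1], 1.0)
    n_pos = int(pos.sum())
    S_g = cfg.scale_g if cfg.scale_g is not None else _default_scale(cfg.df_g, 0.5)

    prev = float(np.mean(labels))
    beta0 = float(special.ndtri(np.clip(prev, 0.01, 0.99)))
    alpha = np.zeros(n)
    s2g = 0.5
    is_one = np.zeros(n, dtype=bool)
    is_one[obs] = labels == 1.0

    acc = {"beta0": 0.0, "s2g": 0.0}
    g_sum = np.zeros(n)
    phi_sum = np.zeros(n)
    eta_sum = np.zeros(n)
    retained = 0

    for it in range(cfg.n_iter):
        g = U @ alpha
        eta = beta0 + g
        # liabilities: truncated for observed labels, free for masked lines
        liab = _sample_trunc_normal(rng, eta, is_one)
        free = ~obs
        if free.any():
            # overwrite masked entries with unconstrained draws
            liab[free] = eta[free] + rng.standard_normal(int(free.sum()))
        # intercept (flat prior, residual variance 1)
        beta0 = float(np.mean(liab - g)) + rng.standard_normal() / np.sqrt(n)
        # genomic effect in the eigenbasis
        rt = U.T @ (liab - beta0)
        prec = np.where(pos, 1.0 + 1.0 / (s2g * np.maximum(d, _EIG_TOL)), np.inf)
        mean_a = np.where(pos, rt / prec, 0.0)
        sd_a = np.where(pos, np.sqrt(1.0 / prec), 0.0)
        alpha = mean_a + sd_a * rng.standard_normal(n)
        ssg = float(np.sum(alpha[pos] ** 2 / d[pos]))
        s2g = _scaled_inv_chi2(rng, cfg.df_g, cfg.df_g * S_g, n_pos, ssg)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            retained += 1
            g = U @ alpha
            eta = beta0 + g
            acc["beta0"] += beta0
            acc["s2g"] += s2g
            g_sum += g
            eta_sum += eta
            phi_sum += special.ndtr(eta)

    return TGBLUPFit(
        beta0=acc["beta0"] / retained,
        g_hat=g_sum / retained,
        sigma2_g=acc["s2g"] / retained,
        train_ids=train_ids,
        all_ids=all_ids,
        mcmc_meta={**asdict(cfg), "n_retained": retained},
        proba_mean_phi=phi_sum / retained,
        proba_phi_mean=special.ndtr(eta_sum / retained),
    )


def predict_tgblup_proba(fit: TGBLUPFit, ids, proba_mode: str = None) -> np.ndarray:
    """Class-1 probabilities for the requested line ids.

    ``posterior_mean_of_phi`` (default) averages ``Phi(beta0 + g_i)`` over
    retained samples; ``phi_of_posterior_mean`` applies ``Phi`` to the
    posterior-mean linear predictor.
    """
    mode = proba_mode or fit.proba_mode
    if mode == "posterior_mean_of_phi":
        src = fit.proba_mean_phi
    elif mode == "phi_of_posterior_mean":
        src = fit.proba_phi_mean
    else:
        raise ModelError(f"unknown proba_mode {mode!r}")
    index = {l: k for k, l in enumerate(fit.all_ids)}
    try:
        sel = [index[i] for i in ids]
    except KeyError as exc:
        raise ModelError(f"unknown line id {exc.args[0]!r}") from None
    return src[sel]
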