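"""Parametric empirical-Bayes ComBat harmonization of tract FA profiles.

Removes per-site location and scale effects from subjects x features
matrices while preserving designated biological covariates (e.g. age,
sex, diagnosis). Implements the standard parametric ComBat model: each
feature is standardized against a covariate-adjusted grand mean and
pooled variance, per-site location/scale effects are estimated and
shrunk toward normal / inverse-gamma priors with method-of-moments
hyperparameters, iterating the conditional posterior means to
convergence.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["CombatHarmonizer", "fit_combat", "apply_combat"]


def _as_2d(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X
    return np.asarray(X, dtype=float), None


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(s_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=100):
    """Iterate EB posterior means for one site until convergence."""
    n = s_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


class CombatHarmonizer(BaseEstimator, TransformerMixin):
    """Empirical-Bayes location/scale batch harmonizer (parametric ComBat).

    Parameters
    ----------
    eb : bool, default True
        Shrink per-site estimates via the normal / inverse-gamma priors.
        With ``eb=False`` the raw per-site estimates are used (no
        shrinkage), useful for exact checks on planted effects.
    conv : float, default 1e-4
        Relative convergence tolerance on successive posterior estimates.
    max_iter : int, default 100
        Maximum EB iterations per site.

    Attributes (after fit)
    ----------------------
    sites_ : list of site labels (roster)
    grand_mean_ : (p,) covariate-free grand mean per feature
    beta_cov_ : (q, p) covariate coefficients per feature
    var_pooled_ : (p,) pooled residual variance per feature
    gamma_star_, delta_star_ : (G, p) shrunken site location / scale
        estimates in standardized units
    """

    def __init__(self, eb: bool = True, conv: float = 1e-4, max_iter: int = 100):
        self.eb = eb
        self.conv = conv
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None, *, site, covariates=None):
        V, _ = _as_2d(X)
        if not np.all(np.isfinite(V)):
            raise ValueError("X contains non-finite values")
        site = np.asarray(site)
        if len(site) != V.shape[0]:
            raise ValueError("site labels must match the number of subjects")
        sites, site_idx = np.unique(site, return_inverse=True)
        counts = np.bincount(site_idx)
        if len(sites) > 1 and np.any(counts < 2):
            bad = sites[counts < 2]
            raise ValueError(
                f"site(s) with a single subject (scale undefined): {list(bad)}"
            )

        n, p = V.shape
        self.sites_ = list(sites)
        self.n_features_in_ = p

        if len(sites) == 1:
            # no batch effect to remove: identity transform
            self.identity_ = True
            return self
        self.identity_ = False

        C_raw = self._covariate_matrix(covariates, n)
        self.cov_mean_ = C_raw.mean(axis=0) if C_raw is not None else None
        C = C_raw - self.cov_mean_ if C_raw is not None else None
        B = np.zeros((n, len(sites)))
        B[np.arange(n), site_idx] = 1.0
        D = np.hstack([B, C]) if C is not None else B
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError(
                "singular design: covariates must exclude site indicators "
                "and be full rank"
            )
        beta, *_ = np.linalg.lstsq(D, V, rcond=None)
        g = len(sites)
        batch_means = beta[:g]
        self.beta_cov_ = beta[g:] if C is not None else np.zeros((0, p))
        self.grand_mean_ = (counts / n) @ batch_means
        resid = V - D @ beta
        self.var_pooled_ = (resid**2).mean(axis=0)
        if np.any(self.var_pooled_ <= 0):
            raise ValueError("zero pooled variance: constant feature(s)")

        stand_mean = self.grand_mean_[None, :] + (
            C @ self.beta_cov_ if C is not None else 0.0
        )
        s_data = (V - stand_mean) / np.sqrt(self.var_pooled_)[None, :]

        gamma_hat = np.vstack(
            [s_data[site_idx == k].mean(axis=0) for k in range(g)]
        )
        delta_hat = np.vstack(
            [s_data[site_idx == k].var(axis=0, ddof=1) for k in range(g)]
        )
        self.gamma_hat_, self.delta_hat_ = gamma_hat, delta_hat

        if self.eb:
            gamma_star = np.empty_like(gamma_hat)
            delta_star = np.empty_like(delta_hat)
            for k in range(g):
                g_bar = gamma_hat[k].mean()
                t2 = gamma_hat[k].var(ddof=1)
                a, b = _aprior(delta_hat[k]), _bprior(delta_hat[k])
                gamma_star[k], delta_star[k] = _it_sol(
                    s_data[site_idx == k],
                    gamma_hat[k],
                    delta_hat[k],
                    g_bar,
                    t2,
                    a,
                    b,
                    conv=self.conv,
                    max_iter=self.max_iter,
                )
        else:
            gamma_star, delta_star = gamma_hat, delta_hat
        self.gamma_star_, self.delta_star_ = gamma_star, delta_star
        return self

    def _covariate_matrix(self, covariates, n):
        if covariates is None:
            return None
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows must match the number of subjects")
        return C

    # -- transform ---------------------------------------------------------
    def transform(self, X, *, site, covariates=None):
        V, frame = _as_2d(X)
        if self.identity_:
            return X.copy() if frame is not None else V.copy()
        site = np.asarray(site)
        unseen = set(np.unique(site)) - set(self.sites_)
        if unseen:
            raise ValueError(f"unseen site label(s): {sorted(map(str, unseen))}")
        lookup = {s: k for k, s in enumerate(self.sites_)}
        site_idx = np.array([lookup[s] for s in site])

        n = V.shape[0]
        C = self._covariate_matrix(covariates, n)
        if (C is None) != (self.cov_mean_ is None):
            raise ValueError("covariates must match those used at fit time")
        if C is not None:
            if C.shape[1] != len(self.cov_mean_):
                raise ValueError("covariate count must match fit time")
            C = C - self.cov_mean_  # centered on training covariate means
        stand_mean = self.grand_mean_[None, :] + (
            C @ self.beta_cov_ if C is not None else 0.0
        )
        s_data = (V - stand_mean) / np.sqrt(self.var_pooled_)[None, :]
        adj = (s_data - self.gamma_star_[site_idx]) / np.sqrt(
            self.delta_star_[site_idx]
        )
        out = adj * np.sqrt(self.var_pooled_)[None, :] + stand_mean
        if frame is not None:
            return pd.DataFrame(out, index=frame.index, columns=frame.columns)
        return out

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, **kwargs).transform(X, **kwargs)

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        state = {"eb": self.eb, "conv": self.conv, "max_iter": self.max_iter,
                 "identity": self.identity_, "sites": [str(s) for s in self.sites_],
                 "n_features": self.n_features_in_}
        if not self.identity_:
            state.update(
                cov_mean=None if self.cov_mean_ is None else self.cov_mean_.tolist(),
                grand_mean=self.grand_mean_.tolist(),
                beta_cov=self.beta_cov_.tolist(),
                var_pooled=self.var_pooled_.tolist(),
                gamma_star=self.gamma_star_.tolist(),
                delta_star=self.delta_star_.tolist(),
            )
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def from_json(cls, path) -> "CombatHarmonizer":
        with open(path) as fh:
            state = json.load(fh)
        model = cls(eb=state["eb"], conv=state["conv"], max_iter=state["max_iter"])
        model.identity_ = state["identity"]
        model.sites_ = state["sites"]
        model.n_features_in_ = state["n_features"]
        if not model.identity_:
            cm = state["cov_mean"]
            model.cov_mean_ = None if cm is None else np.array(cm)
            model.grand_mean_ = np.array(state["grand_mean"])
            model.beta_cov_ = np.array(state["beta_cov"])
            model.var_pooled_ = np.array(state["var_pooled"])
            model.gamma_star_ = np.array(state["gamma_star"])
            model.delta_star_ = np.array(state["delta_star"])
        return model


def fit_combat(profiles, site, covariates=None, **kwargs) -> CombatHarmonizer:
    """Fit a ComBat model on subjects x features data."""
    return CombatHarmonizer(**kwargs).fit(profiles, site=site, covariates=covariates)


def apply_combat(model: CombatHarmonizer, profiles, site, covariates=None):
    """Apply a fitted ComBat model; preserves feature count and subject order."""
    return model.transform(profiles, site=site, covariates=covariates)
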