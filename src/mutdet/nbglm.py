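"""Negative-binomial GLM with log link and exposure offset.

The model for per-gene mutation counts is

    y_i ~ NB2(mu_i, theta),   log(mu_i) = beta0 + sum_j beta_j x_ij + log(L_i)

with variance mu + mu^2/theta, so theta -> infinity recovers Poisson
regression.  log(L_i) is the exposure offset (number of mutable sites),
making exp(beta_j) a per-site rate ratio per SD of covariate j.

Fitting alternates iteratively reweighted least squares for beta at fixed
theta with Newton steps on the profile likelihood of log(theta), the same
scheme R's glm.nb uses.  Standard errors for beta come from the expected
information at the optimum (conditional on theta); the dispersion SE from
the second derivative of the profile log-likelihood.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg, special, stats
from sklearn.base import BaseEstimator

__all__ = ["NegativeBinomialGLM", "nb_loglik"]

_ETA_MAX = 30.0  # exp(30) ~ 1e13 counts; anything larger is a modelling error


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood (exact, including constant terms)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    ))


def _theta_score_hess(y, mu, theta):
    s = np.sum(special.digamma(y + theta) - special.digamma(theta)
               + np.log(theta) + 1 - np.log(theta + mu)
               - (y + theta) / (theta + mu))
    h = np.sum(special.polygamma(1, y + theta) - special.polygamma(1, theta)
               + 1 / theta - 2 / (theta + mu)
               + (y + theta) / (theta + mu) ** 2)
    return float(s), float(h)


def _check_rank(X: np.ndarray, names) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise ValueError(f"rank-deficient design: collinear column(s) {bad}")


class NegativeBinomialGLM(BaseEstimator):
    """Negative-binomial count regression with a log link.

    Parameters
    ----------
    theta : float or None
        NB size (dispersion) parameter.  None (default) estimates it by
        maximum likelihood jointly with the coefficients; a fixed value
        skips dispersion estimation (large values approximate Poisson).
    fit_intercept : bool
        Prepend a constant column.
    max_iter : int
        Maximum outer (beta/theta alternation) iterations.
    tol : float
        Relative coefficient-change tolerance for the inner IRLS and the
        outer log-likelihood change tolerance.
    theta_max : float
        Cap on the estimated dispersion; hitting it flags the fit as the
        Poisson limit rather than failing.

    Attributes
    ----------
    coef_ : ndarray of covariate coefficients (excludes intercept)
    intercept_ : float
    theta_ : float, estimated (or fixed) dispersion
    params_, bse_, zvalues_, pvalues_ : full coefficient table arrays,
        intercept first when fitted
    theta_se_ : float or nan
    loglik_ : float
    converged_ : bool
    grad_norm_ : float, L2 norm of the beta score at the optimum
    n_iter_ : int
    """

    def __init__(self, theta: float | None = None, fit_intercept: bool = True,
                 max_iter: int = 100, tol: float = 1e-10,
                 theta_max: float = 1e8):
        self.theta = theta
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.theta_max = theta_max

    # -- internals ---------------------------------------------------------
    def _irls(self, X, y, offset, theta, beta):
        for _ in range(200):
            eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
            mu = np.exp(eta)
            w = mu / (1.0 + mu / theta)
            z = (eta - offset) + (y - mu) / mu
            wx = X * w[:, None]
            new = linalg.solve(X.T @ wx, wx.T @ z, assume_a="pos")
            delta = np.max(np.abs(new - beta)) / max(1.0, np.max(np.abs(new)))
            beta = new
            if delta < self.tol:
                break
        return beta

    def _estimate_theta(self, y, mu, theta):
        u = np.log(theta)
        for _ in range(50):
            th = np.exp(u)
            s, h = _theta_score_hess(y, mu, th)
            du_score = th * s
            du_hess = th * th * h + th * s
            if du_hess >= 0:  # not locally concave: damped gradient step
                step = np.sign(du_score) * 0.5
            else:
                step = -du_score / du_hess
            step = np.clip(step, -2.0, 2.0)
            u_new = u + step
            if np.exp(u_new) > self.theta_max:
                return self.theta_max, True
            if np.exp(u_new) < 1e-8:
                u_new = np.log(1e-8)
            if abs(u_new - u) < 1e-10:
                u = u_new
                break
            u = u_new
        return float(np.exp(u)), False

    # -- API ---------------------------------------------------------------
    def fit(self, X, y, offset=None, feature_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        n, k = X.shape
        if len(y) != n:
            raise ValueError("X and y length mismatch")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("counts must be non-negative integers")
        if offset is None:
            offset = np.zeros(n)
        offset = np.asarray(offset, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j + 1}" for j in range(k)]
        names = (["intercept"] if self.fit_intercept else []) + list(feature_names)
        D = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        _check_rank(D, names)

        # moment initialization
        mu0 = np.maximum(y, 0.5)
        beta = np.zeros(D.shape[1])
        if self.fit_intercept:
            beta[0] = np.log(np.mean(mu0 / np.exp(np.clip(offset, -_ETA_MAX, _ETA_MAX))))
        if self.theta is not None:
            theta = float(self.theta)
        else:
            beta = self._irls(D, y, offset, 1e4, beta)  # quasi-Poisson start
            mu = np.exp(np.clip(D @ beta + offset, -_ETA_MAX, _ETA_MAX))
            denom = np.sum(np.maximum((y - mu) ** 2 - mu, 0))
            theta = float(np.sum(mu ** 2) / denom) if denom > 0 else 10.0
            theta = float(np.clip(theta, 1e-3, self.theta_max))

        hit_cap = False
        ll_old = -np.inf
        n_outer = 0
        for n_outer in range(1, self.max_iter + 1):
            beta = self._irls(D, y, offset, theta, beta)
            mu = np.exp(np.clip(D @ beta + offset, -_ETA_MAX, _ETA_MAX))
            if self.theta is None:
                theta, hit_cap = self._estimate_theta(y, mu, theta)
            ll = nb_loglik(y, mu, theta)
            if abs(ll - ll_old) < max(1.0, abs(ll)) * 1e-12:
                ll_old = ll
                break
            ll_old = ll
            if self.theta is not None and n_outer >= 2:
                break

        beta = self._irls(D, y, offset, theta, beta)  # polish at final theta
        mu = np.exp(np.clip(D @ beta + offset, -_ETA_MAX, _ETA_MAX))
        score = D.T @ ((y - mu) / (1.0 + mu / theta))
        grad_norm = float(np.linalg.norm(score))
        w = mu / (1.0 + mu / theta)
        info = D.T @ (D * w[:, None])
        cov = linalg.inv(info)
        bse = np.sqrt(np.diag(cov))

        self.params_ = beta
        self.bse_ = bse
        self.zvalues_ = beta / bse
        self.pvalues_ = 2 * stats.norm.sf(np.abs(self.zvalues_))
        self.term_names_ = names
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.theta_ = float(theta)
        if self.theta is None and not hit_cap:
            _, h = _theta_score_hess(y, mu, theta)
            self.theta_se_ = float(np.sqrt(-1.0 / h)) if h < 0 else float("nan")
        else:
            self.theta_se_ = float("nan")
        self.loglik_ = nb_loglik(y, mu, theta)
        self.n_iter_ = n_outer
        self.poisson_limit_ = bool(hit_cap)
        scale = max(1.0, float(np.sqrt(np.sum(w))))  # score scales with n
        self.grad_norm_ = grad_norm
        self.converged_ = bool(grad_norm / scale < 1e-6)
        self.cov_params_ = cov
        self.n_features_in_ = k
        if not self.converged_:
            warnings.warn(
                f"NegativeBinomialGLM did not converge (grad norm {grad_norm:.3g})")
        return self

    def predict(self, X, offset=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = X @ self.coef_ + self.intercept_
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return np.exp(eta)
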