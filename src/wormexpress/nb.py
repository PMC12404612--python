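"""Negative-binomial mixed model with a random intercept, fitted by PQL.

Per-gene counts are modelled as

    y_i ~ NB(mu_i, theta),   log mu_i = x_i' b + u_group(i) + offset_i

with Var(y) = mu + mu^2 / theta (so larger theta means closer to
Poisson) and u_j ~ N(0, sigma2_u) a biological-replicate intercept.

Fitting alternates penalized quasi-likelihood steps — a working linear
mixed model on the linkscale response z = eta + (y - mu)/mu with
weights w = mu / (1 + mu/theta) — with one-dimensional maximum-likelihood
updates of the dispersion theta at the current fitted means.  No
installed Python library fits this model (statsmodels has NB GLMs but no
NB mixed model), hence the in-house routine; tests cross-check the
coefficients against lme4::glmer-style generative truth on simulated
counts.

The working residual (y - mu)/mu lives on the log scale (delta method),
so its sample variance is reported as the gene's *unexplained variance*:
expression variability left over after environment fixed effects and the
replicate intercept are accounted for.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

from .lmm import RandomInterceptLMM

__all__ = ["NegativeBinomialMixedModel"]


def _nb_negloglik(log_theta: float, y: np.ndarray, mu: np.ndarray) -> float:
    th = np.exp(log_theta)
    ll = (special.gammaln(y + th) - special.gammaln(th) - special.gammaln(y + 1.0)
          + th * np.log(th / (th + mu)) + y * np.log(mu / (th + mu)))
    return -float(np.sum(ll))


class NegativeBinomialMixedModel:
    """NB regression with log link and one random intercept (PQL).

    Parameters
    ----------
    fit_intercept : bool
    max_iter : int
        Outer PQL iterations.
    tol : float
        Convergence tolerance on the fixed-effect vector.
    theta_init : float
        Starting dispersion.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_, params_, bse_, pvalues_ : fixed-effect inference
        (Wald t with df = n - p - n_groups, matching the LMM engine)
    theta_ : dispersion (Var = mu + mu^2/theta)
    sigma2_u_ : replicate-intercept variance on the log scale
    unexplained_variance_ : variance of log-scale working residuals
    converged_ : bool
    """

    def __init__(self, fit_intercept: bool = True, max_iter: int = 60,
                 tol: float = 1e-6, theta_init: float = 10.0):
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.theta_init = theta_init

    def get_params(self, deep: bool = True):
        return {"fit_intercept": self.fit_intercept, "max_iter": self.max_iter,
                "tol": self.tol, "theta_init": self.theta_init}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, groups=None, offset=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        if X.shape[0] != n:
            X = X.T
        if np.any(y < 0):
            raise ValueError("negative counts")
        offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
        groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)

        theta = float(self.theta_init)
        mu = np.maximum(y, 0.5)
        eta = np.log(mu)
        params_prev = None
        converged = False
        wlmm = RandomInterceptLMM(method="reml", fit_intercept=self.fit_intercept,
                                  df_rule="residual", profile_scale=False)
        for it in range(self.max_iter):
            z = (eta - offset) + (y - mu) / mu
            w = mu / (1.0 + mu / theta)
            wlmm.fit(X, z, groups=groups, weights=w)
            eta = wlmm.predict(X, groups=groups) + offset
            eta = np.clip(eta, -30.0, 30.0)
            mu = np.exp(eta)
            # dispersion update by profile ML at current means
            res = optimize.minimize_scalar(
                _nb_negloglik, bounds=(np.log(1e-3), np.log(1e6)),
                method="bounded", args=(y, mu), options={"xatol": 1e-6})
            theta = float(np.exp(res.x))
            if params_prev is not None and np.max(np.abs(wlmm.params_ - params_prev)) < self.tol:
                converged = True
                break
            params_prev = wlmm.params_.copy()

        self.params_ = wlmm.params_
        self.bse_ = wlmm.bse_
        self.tvalues_ = wlmm.tvalues_
        self.pvalues_ = wlmm.pvalues_
        self.coef_ = wlmm.coef_
        self.intercept_ = wlmm.intercept_
        self.sigma2_u_ = wlmm.sigma2_u_
        self.theta_ = theta
        self.df_resid_ = wlmm.df_resid_
        self.converged_ = converged
        self.mu_ = mu
        work_resid = (y - mu) / mu
        self.unexplained_variance_ = float(np.var(work_resid, ddof=1))
        return self

    def predict(self, X, groups=None, offset=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = X @ self.coef_ + self.intercept_
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return np.exp(eta)
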