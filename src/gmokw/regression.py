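"""Unit quantile regression with the quantile-reparameterized GMOKW (QGMOKW).

The GMOKW quantile function is inverted in its first Kumaraswamy shape:
fixing a level p and a target quantile mu in (0,1),

    kappa* = log(1 - (1 - z_p)^(1/gamma)) / log(mu),

where z_p is the root of the Marshall-Olkin quadratic at level p, makes
mu the p-th quantile of GMOKW(alpha, lambda, kappa*, gamma) by
construction.  Regressing the conditional quantile through a logit link,
mu_i = expit(x_i' beta), yields a parametric quantile-regression model
for bounded responses whose coefficients act on the log-odds of the
conditional p-quantile.  The default p = 0.5 gives median regression.

Inference is maximum likelihood: the observed information matrix J
(negative Hessian of the log-likelihood at the optimum, numerically
differentiated) gives V = J^{-1}, Wald standard errors, z-statistics,
and two-sided normal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from ._utils import from_unconstrained, latin_hypercube_starts, to_unconstrained
from .distributions import UnitSample, gmokw_logpdf
from .distributions import _z_root  # Marshall-Olkin quadratic root

__all__ = ["kappa_star", "qgmokw_logpdf", "regression_negloglik", "fit_regression",
           "RegressionModel", "GMOKWQuantileRegressor"]

_PENALTY = 1e12


def kappa_star(mu, p, alpha, lam, gamma):
    """Kumaraswamy shape that places the p-th quantile at mu.

    Satisfies gmokw_cdf(mu; alpha, lam, kappa*, gamma) = p by construction.
    """
    mu = np.asarray(mu, dtype=float)
    z = _z_root(np.asarray(p, dtype=float), alpha, lam)
    log_t = np.log(-np.expm1(np.log1p(-z) / gamma))  # log(1-(1-z_p)^(1/gamma)) < 0
    out = log_t / np.log(mu)
    return out if out.ndim else float(out)


def qgmokw_logpdf(t, mu, p, alpha, lam, gamma):
    """Log-density of the quantile-reparameterized GMOKW.

    Pure substitution: equals gmokw_logpdf at (alpha, lam, kappa*, gamma).
    """
    ks = kappa_star(mu, p, alpha, lam, gamma)
    return gmokw_logpdf(t, (alpha, lam, ks, gamma))


def _mu_from_eta(eta):
    return 1.0 / (1.0 + np.exp(-eta))


def regression_negloglik(phi, t, X, p=0.5):
    """Negative log-likelihood of Phi = (alpha, lam, gamma, beta_0..beta_p)."""
    phi = np.asarray(phi, dtype=float)
    alpha, lam, gamma = phi[0], phi[1], phi[2]
    beta = phi[3:]
    if not (0 < alpha < 1 and 0 < lam < 1 and gamma > 0):
        return _PENALTY
    eta = X @ beta
    if np.any(np.abs(eta) > 35):  # mu indistinguishable from 0/1
        return _PENALTY
    mu = _mu_from_eta(eta)
    lp = qgmokw_logpdf(t, mu, p, alpha, lam, gamma)
    if not np.all(np.isfinite(lp)):
        return _PENALTY
    return -float(np.sum(lp))


@dataclass
class RegressionModel:
    """Fitted QGMOKW quantile-regression model."""

    phi: np.ndarray          # (alpha, lam, gamma, beta...)
    p: float
    X: np.ndarray
    mu: np.ndarray           # fitted conditional p-quantiles
    loglik: float
    aic: float
    J: Optional[np.ndarray]  # observed information
    V: Optional[np.ndarray]  # inverse observed information
    se: Optional[np.ndarray]
    z: Optional[np.ndarray]
    p_values: Optional[np.ndarray]
    converged: bool
    param_names: list

    @property
    def alpha(self):
        return self.phi[0]

    @property
    def lam(self):
        return self.phi[1]

    @property
    def gamma(self):
        return self.phi[2]

    @property
    def beta(self):
        return self.phi[3:]

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, z, two-sided p-value."""
        k = len(self.phi)
        se = self.se if self.se is not None else np.full(k, np.nan)
        z = self.z if self.z is not None else np.full(k, np.nan)
        pv = self.p_values if self.p_values is not None else np.full(k, np.nan)
        return pd.DataFrame(
            {"estimate": self.phi, "se": se, "z": z, "p_value": pv},
            index=self.param_names,
        )


def fit_regression(t, X, p=0.5, n_starts=12, seed=20240101) -> RegressionModel:
    """Fit the QGMOKW quantile-regression model by maximum likelihood.

    Parameters are optimized over (logit alpha, logit lam, log gamma,
    beta) with multi-start Nelder-Mead plus L-BFGS-B polish.  Starting
    betas come from an OLS fit of logit(t) on X; the distributional
    parameters start at the Kumaraswamy collapse alpha = lam.
    """
    t = np.asarray(t.values if isinstance(t, UnitSample) else t, dtype=float).ravel()
    UnitSample(t)  # validate the support
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != t.size:
        raise ValueError("X must be n x (p+1) with rows matching the response")
    n, k_beta = X.shape
    if n <= 3 + k_beta:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < k_beta:
        raise ValueError("design matrix is rank-deficient")
    if not (0.0 < p < 1.0):
        raise ValueError("quantile level p must lie in (0,1)")

    kinds = ["unit", "unit", "pos"] + ["free"] * k_beta

    def obj_t(theta):
        return regression_negloglik(from_unconstrained(theta, kinds), t, X, p)

    # OLS of logit(t) on X for the beta start
    lt = np.log(t / (1.0 - t))
    beta0, *_ = np.linalg.lstsq(X, lt, rcond=None)
    base = to_unconstrained(np.concatenate([[0.5, 0.5, 1.0], beta0]), kinds)

    dist_bounds = [(-3.0, 3.0), (-3.0, 3.0), (np.log(0.2), np.log(20.0))]
    lhs = latin_hypercube_starts(max(n_starts - 1, 1), dist_bounds, seed)
    starts = [base]
    for row in lhs:
        th = base.copy()
        th[:3] = row
        starts.append(th)

    results = []
    with np.errstate(all="ignore"):
        for x0 in starts:
            r = optimize.minimize(obj_t, x0, method="Nelder-Mead",
                                  options={"maxiter": 400 * len(x0), "fatol": 1e-9,
                                           "xatol": 1e-7})
            results.append(r)
        results.sort(key=lambda r: (r.fun, tuple(r.x)))
        polished = []
        for r in results[:3]:
            pr = optimize.minimize(obj_t, r.x, method="L-BFGS-B",
                                   options={"maxfun": 4000, "ftol": 1e-13, "gtol": 1e-10})
            polished.append(pr)
        polished.sort(key=lambda r: (r.fun, tuple(r.x)))
        best = polished[0]

    phi = from_unconstrained(best.x, kinds)
    nll = float(best.fun)
    loglik = -nll
    k = phi.size
    aic = 2 * nll + 2 * k
    names = ["alpha", "lambda", "gamma"] + [f"beta{j}" for j in range(k_beta)]

    # Observed information on the unconstrained scale (numerically well
    # conditioned even when alpha/lambda sit near a boundary), mapped back
    # to the original parameterization by the delta method.
    # Observed information on the unconstrained scale (numerically well
    # conditioned even when alpha/lambda sit near a boundary), mapped back
    # to the original parameterization by the delta method.  A tilt
    # parameter can saturate on a likelihood ridge, leaving a null
    # information direction: those components get SE = NaN while the
    # identified block (in particular the regression coefficients) keeps
    # valid Wald inference.
    J = V = se = zst = pv = None
    try:
        with np.errstate(all="ignore"):
            H_t = approx_hess1(best.x, obj_t)
            w, Q = np.linalg.eigh(H_t)
        tol = 1e-8 * np.max(np.abs(w))
        identified = w > tol
        if np.any(identified):
            inv_w = np.where(identified, 1.0 / np.where(identified, w, 1.0), 0.0)
            V_t = (Q * inv_w) @ Q.T
            null_load = np.abs(Q[:, ~identified]).sum(axis=1) if np.any(~identified) \
                else np.zeros(len(phi))
            grad = np.ones_like(phi)
            grad[0] = phi[0] * (1.0 - phi[0])   # d expit / d theta
            grad[1] = phi[1] * (1.0 - phi[1])
            grad[2] = phi[2]                    # d exp / d theta
            V = V_t * np.outer(grad, grad)
            d = np.diag(V).copy()
            d[null_load > 1e-3] = np.nan
            d[d <= 0] = np.nan
            se = np.sqrt(d)
            J = H_t
            with np.errstate(all="ignore"):
                zst = phi / se
                pv = 2.0 * stats.norm.sf(np.abs(zst))
            if not np.any(np.isfinite(se)):
                J = V = se = zst = pv = None
            elif np.any(~identified):
                import warnings

                warnings.warn("information matrix is singular along a ridge; "
                              "SEs for unidentified components reported as NaN",
                              RuntimeWarning)
    except Exception:
        pass

    mu = _mu_from_eta(X @ phi[3:])
    return RegressionModel(phi, float(p), X, mu, loglik, aic, J, V, se, zst, pv,
                           converged=nll < _PENALTY / 2, param_names=names)


class GMOKWQuantileRegressor:
    """Scikit-learn style quantile regressor for (0,1)-bounded responses.

    Parameters
    ----------
    p : float
        Quantile level in (0,1); 0.5 gives median regression.
    fit_intercept : bool
        Prepend a column of ones to X (default True).
    n_starts : int
        Multi-start count for the distributional parameters.
    random_state : int
        Seed for the starting-point sample.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : regression coefficients on the logit scale
    alpha_, lambda_, gamma_ : fitted distributional parameters
    se_, z_, p_values_ : Wald inference per parameter
    loglik_, aic_ : fit quality
    model_ : the full RegressionModel
    """

    def __init__(self, p=0.5, fit_intercept=True, n_starts=12, random_state=20240101):
        self.p = p
        self.fit_intercept = fit_intercept
        self.n_starts = n_starts
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"p": self.p, "fit_intercept": self.fit_intercept,
                "n_starts": self.n_starts, "random_state": self.random_state}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y):
        Xd = self._design(X)
        m = fit_regression(y, Xd, p=self.p, n_starts=self.n_starts,
                           seed=self.random_state)
        self.model_ = m
        self.alpha_, self.lambda_, self.gamma_ = m.alpha, m.lam, m.gamma
        if self.fit_intercept:
            self.intercept_, self.coef_ = m.beta[0], m.beta[1:]
        else:
            self.intercept_, self.coef_ = 0.0, m.beta
        self.se_, self.z_, self.p_values_ = m.se, m.z, m.p_values
        self.loglik_, self.aic_ = m.loglik, m.aic
        return self

    def predict(self, X):
        """Fitted conditional p-quantiles for new covariate rows."""
        Xd = self._design(X)
        return _mu_from_eta(Xd @ self.model_.beta)

    def score(self, X, y):
        """Mean log-likelihood of (X, y) under the fitted model."""
        Xd = self._design(X)
        m = self.model_
        mu = _mu_from_eta(Xd @ m.beta)
        return float(np.mean(qgmokw_logpdf(np.asarray(y, float), mu, m.p,
                                           m.alpha, m.lam, m.gamma)))
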