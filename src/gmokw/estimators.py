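"""Classical estimators for unit distributions.

Nine estimation objectives are provided, all phrased as minimizations over
an unconstrained transform of the parameter space (logit for (0,1)-valued
parameters, log for positive shapes):

    MLE     negative log-likelihood
    LSE     sum (F_i - i/(n+1))^2
    WLSE    sum w_i (F_i - i/(n+1))^2,  w_i = (n+1)^2 (n+2) / [i (n-i+1)]
    ADE     -n - (1/n) sum (2i-1) [log F_i + log(1 - F_{n+1-i})]
    CvME    1/(12n) + sum (F_i - (2i-1)/(2n))^2
    MPSE    -(1/(n+1)) sum log D_i           (negated mean log-spacing)
    RTADE   n/2 - 2 sum F_i - (1/n) sum (2i-1) log(1 - F_{n+1-i})
    MSADE   sum |D_i - 1/(n+1)|
    MSALDE  sum |log D_i - log(1/(n+1))|

where F_i is the fitted cdf at the i-th order statistic and D_i are the
n+1 spacings of the fitted cdf over the augmented order statistics
(F(y_(0)) = 0, F(y_(n+1)) = 1).  Tied observations make a spacing vanish;
following the Cheng-Amin convention the corresponding log D_i is replaced
by the log-density at the tied point, which keeps the spacing objectives
finite on real data with repeated values.

Optimization is multi-start: a moment/baseline-matched start plus a seeded
Latin hypercube of transformed starting points, each refined by Nelder-Mead
and the best polished by L-BFGS-B.  The four-parameter GMOKW likelihood is
flat and can be multimodal, hence the generous default of 40 starts for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess1

from ._utils import from_unconstrained, latin_hypercube_starts, to_unconstrained
from .competitors import Family, get_family
from .distributions import UnitSample

__all__ = [
    "METHODS",
    "FitResult",
    "negloglik",
    "spacings",
    "estimation_objective",
    "fit",
    "UnitDistributionFitter",
]

METHODS = ("mle", "lse", "wlse", "ade", "cvme", "mpse", "rtade", "msade", "msalde")

_PENALTY = 1e12
_EPS = 1e-12

DEFAULT_SEED = 20240101


def _as_sample(sample) -> UnitSample:
    return sample if isinstance(sample, UnitSample) else UnitSample(np.asarray(sample))


def negloglik(params, sample, family="gmokw"):
    """Negative log-likelihood; large penalty if any density underflows."""
    fam = get_family(family)
    y = _as_sample(sample).values
    lp = fam.logpdf(y, np.asarray(params, dtype=float))
    if not np.all(np.isfinite(lp)):
        return _PENALTY
    return -float(np.sum(lp))


def spacings(params, sample, family="gmokw"):
    """Spacings D_i (i = 1..n+1) of the fitted cdf over augmented order stats."""
    fam = get_family(family)
    ys = _as_sample(sample).sorted_values
    F = np.clip(fam.cdf(ys, np.asarray(params, dtype=float)), 0.0, 1.0)
    return np.diff(np.concatenate(([0.0], F, [1.0])))


def _log_spacings(params, sample, family):
    """log D_i with the tie rule: vanished interior spacings use log f(y_(i))."""
    fam = get_family(family)
    s = _as_sample(sample)
    ys = s.sorted_values
    p = np.asarray(params, dtype=float)
    F = np.clip(fam.cdf(ys, p), 0.0, 1.0)
    D = np.diff(np.concatenate(([0.0], F, [1.0])))
    if np.any(D < 0):  # non-monotone cdf evaluation: reject the point
        return None
    logD = np.log(np.maximum(D, 1e-300))
    tied = np.concatenate(([False], np.diff(ys) <= 0.0, [False]))
    if np.any(tied):
        lp = fam.logpdf(ys, p)
        logD[tied] = lp[np.nonzero(tied)[0] - 1]
    return logD


def estimation_objective(method, params, sample, family="gmokw"):
    """Evaluate one of the nine objectives (all minimized)."""
    method = str(method).lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    fam = get_family(family)
    s = _as_sample(sample)
    ys = s.sorted_values
    n = s.n
    p = np.asarray(params, dtype=float)

    if method == "mle":
        return negloglik(p, s, family)

    if method in ("mpse", "msade", "msalde"):
        if method == "msade":
            D = spacings(p, s, family)
            return float(np.sum(np.abs(D - 1.0 / (n + 1))))
        logD = _log_spacings(p, s, family)
        if logD is None or not np.all(np.isfinite(logD)):
            return _PENALTY
        if method == "mpse":
            return -float(np.mean(logD))
        return float(np.sum(np.abs(logD - np.log(1.0 / (n + 1)))))

    F = np.asarray(fam.cdf(ys, p), dtype=float)
    if not np.all(np.isfinite(F)):
        return _PENALTY
    i = np.arange(1, n + 1)

    if method == "lse":
        return float(np.sum((F - i / (n + 1)) ** 2))
    if method == "wlse":
        w = (n + 1) ** 2 * (n + 2) / (i * (n - i + 1))
        return float(np.sum(w * (F - i / (n + 1)) ** 2))
    if method == "cvme":
        return float(1.0 / (12 * n) + np.sum((F - (2 * i - 1) / (2 * n)) ** 2))

    Fc = np.clip(F, _EPS, 1.0 - _EPS)
    if method == "ade":
        return float(-n - np.sum((2 * i - 1) * (np.log(Fc) + np.log1p(-Fc[n - i]))) / n)
    if method == "rtade":
        return float(n / 2.0 - 2.0 * np.sum(Fc) - np.sum((2 * i - 1) * np.log1p(-Fc[n - i])) / n)
    raise AssertionError("unreachable")


@dataclass
class FitResult:
    """Outcome of a (family, method) fit."""

    family: str
    method: str
    params: np.ndarray
    objective: float
    neg2loglik: float
    converged: bool
    n_starts: int
    se: Optional[np.ndarray] = None
    message: str = ""

    def __repr__(self):
        p = np.array2string(np.asarray(self.params), precision=4)
        return (
            f"FitResult({self.family}/{self.method}: params={p}, "
            f"objective={self.objective:.6g}, -2logL={self.neg2loglik:.6g}, "
            f"converged={self.converged})"
        )


def _build_objective(method, fam, s):
    """Objective closure for the optimizer.

    For GMOKW a dedicated code path precomputes the log-data and inlines the
    density/cdf algebra: the multi-start loops of the simulation harness make
    per-evaluation overhead the dominant cost.
    Equality with :func:`estimation_objective` is covered by tests.
    """
    if fam.name != "gmokw":
        return lambda p: estimation_objective(method, p, s, fam.name)

    ys = s.sorted_values
    n = s.n
    ly = np.log(ys)
    i = np.arange(1, n + 1)
    tied = np.concatenate(([False], np.diff(ys) <= 0.0, [False]))
    any_tied = bool(np.any(tied))
    tied_idx = np.nonzero(tied)[0] - 1

    def logpdf(p):
        a, l, k, g = p
        l1t = np.log1p(-np.exp(k * ly))
        z = -np.expm1(g * l1t)
        num = (1 - a) * (1 - l) * z * z + 2 * a * (1 - l) * z + a * l
        return (np.log(num) - 2 * np.log(a + (1 - a) * z)
                + np.log(k * g) + (k - 1) * ly + (g - 1) * l1t)

    def cdf(p):
        a, l, k, g = p
        z = -np.expm1(g * np.log1p(-np.exp(k * ly)))
        return (l * z + (1 - l) * z * z) / (a + (1 - a) * z)

    if method == "mle":
        def obj(p):
            lp = logpdf(p)
            s_ = np.sum(lp)
            return -float(s_) if np.isfinite(s_) else _PENALTY
        return obj

    if method in ("mpse", "msade", "msalde"):
        log_ninv = np.log(1.0 / (n + 1))

        def obj(p):
            F = np.clip(cdf(p), 0.0, 1.0)
            D = np.diff(np.concatenate(([0.0], F, [1.0])))
            if method == "msade":
                v = np.sum(np.abs(D - 1.0 / (n + 1)))
                return float(v) if np.isfinite(v) else _PENALTY
            logD = np.log(np.maximum(D, 1e-300))
            if any_tied:
                logD[tied] = logpdf(p)[tied_idx]
            if not np.all(np.isfinite(logD)):
                return _PENALTY
            if method == "mpse":
                return -float(np.mean(logD))
            return float(np.sum(np.abs(logD - log_ninv)))
        return obj

    if method == "wlse":
        w = (n + 1) ** 2 * (n + 2) / (i * (n - i + 1))
    pp = i / (n + 1)
    hp = (2 * i - 1) / (2 * n)

    def obj(p):
        F = cdf(p)
        if not np.all(np.isfinite(F)):
            return _PENALTY
        if method == "lse":
            return float(np.sum((F - pp) ** 2))
        if method == "wlse":
            return float(np.sum(w * (F - pp) ** 2))
        if method == "cvme":
            return float(1.0 / (12 * n) + np.sum((F - hp) ** 2))
        Fc = np.clip(F, _EPS, 1.0 - _EPS)
        if method == "ade":
            return float(-n - np.sum((2 * i - 1) * (np.log(Fc) + np.log1p(-Fc[n - i]))) / n)
        return float(n / 2.0 - 2.0 * np.sum(Fc)
                     - np.sum((2 * i - 1) * np.log1p(-Fc[n - i])) / n)
    return obj


def _transformed_bounds(fam: Family):
    out = []
    for kind in fam.kinds:
        if kind == "unit":
            out.append((-5.3, 5.3))      # alpha, lambda in roughly (0.005, 0.995)
        else:
            out.append((np.log(0.05), np.log(500.0)))
    return out


def _gmokw_baseline_start(sample, seed):
    """Start GMOKW at its Kumaraswamy collapse: quick KW fit, alpha=lambda=0.5."""
    y = sample.values
    ly = np.log(y)

    def kw_nll(theta):
        k, g = np.exp(theta)
        l1t = np.log1p(-np.exp(k * ly))
        v = -np.sum(np.log(k * g) + (k - 1) * ly + (g - 1) * l1t)
        return float(v) if np.isfinite(v) else _PENALTY

    with np.errstate(all="ignore"):
        r = optimize.minimize(kw_nll, np.zeros(2), method="Nelder-Mead",
                              options={"fatol": 1e-8, "xatol": 1e-6})
    k, g = np.exp(r.x)
    return np.array([0.5, 0.5, k, g])


def _mle_se(fam, params, sample):
    """SEs from the inverse observed information (numerical Hessian)."""
    p0 = np.asarray(params, dtype=float)
    try:
        H = approx_hess1(p0, lambda p: negloglik(p, sample, fam.name))
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0):
            return None
        return np.sqrt(d)
    except Exception:
        return None


def fit(sample, family="gmokw", method="mle", n_starts=None, seed=DEFAULT_SEED,
        x0=None, _se=True):
    """Fit a unit distribution by one of the nine estimation methods.

    Returns a FitResult with the estimated parameters, the objective value
    at the optimum, -2 log-likelihood at the estimate, and (for MLE)
    standard errors from the observed information matrix.

    If ``x0`` (untransformed parameters) is given it becomes the first
    starting point; with ``n_starts=1`` the optimization is purely local
    around it — this is how the simulation harness tracks the consistent
    root of a multimodal objective.
    """
    fam = get_family(family)
    s = _as_sample(sample)
    method = str(method).lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if s.n < fam.n_params:
        raise ValueError(f"need at least {fam.n_params} observations for {fam.name}")

    if fam.closed_form_mle is not None and method == "mle":
        p = np.atleast_1d(np.asarray(fam.closed_form_mle(s.values), dtype=float))
        nll = negloglik(p, s, fam.name)
        se = _mle_se(fam, p, s) if _se else None
        return FitResult(fam.name, method, p, nll, 2 * nll, True, 0, se)

    if n_starts is None:
        n_starts = 40 if fam.name == "gmokw" else 10

    kinds = fam.kinds
    bounds = _transformed_bounds(fam)
    raw_obj = _build_objective(method, fam, s)

    def obj_t(theta):
        p = from_unconstrained(theta, kinds)
        try:
            val = raw_obj(p)
        except (ValueError, FloatingPointError):
            return _PENALTY
        if not np.isfinite(val):
            return _PENALTY
        return val

    starts = []
    if x0 is not None:
        starts.append(to_unconstrained(fam.validate(x0), kinds))
    if len(starts) < int(n_starts):
        if fam.name == "gmokw":
            starts.append(to_unconstrained(_gmokw_baseline_start(s, seed), kinds))
        elif fam.start is not None:
            starts.append(to_unconstrained(fam.start(s.values), kinds))
    n_lhs = int(n_starts) - len(starts)
    if n_lhs > 0:
        starts.extend(latin_hypercube_starts(n_lhs, bounds, seed))

    results = []
    with np.errstate(all="ignore"):
        for x0 in starts:
            r = optimize.minimize(
                obj_t, x0, method="Nelder-Mead",
                options={"maxiter": 200 * len(x0), "fatol": 1e-8, "xatol": 1e-6},
            )
            results.append(r)
        results.sort(key=lambda r: (r.fun, tuple(r.x)))
        best = results[0]
        # quasi-Newton polish of the top candidates on the transformed scale
        polished = [best]
        for r in results[: min(3, len(results))]:
            pr = optimize.minimize(obj_t, r.x, method="L-BFGS-B",
                                   options={"maxfun": 2000, "ftol": 1e-13, "gtol": 1e-10})
            polished.append(pr)
        polished.sort(key=lambda r: (r.fun, tuple(r.x)))
        best = polished[0]

    params = from_unconstrained(best.x, kinds)
    obj = float(best.fun)
    converged = bool(obj < _PENALTY / 2) and any(r.success for r in polished + results)
    nll = negloglik(params, s, fam.name) if method != "mle" else obj
    se = _mle_se(fam, params, s) if (method == "mle" and _se) else None
    return FitResult(fam.name, method, params, obj, 2 * nll, converged,
                     len(starts), se, best.message if not converged else "")


class UnitDistributionFitter:
    """Scikit-learn style wrapper around :func:`fit`.

    Parameters
    ----------
    family : str
        One of ``gmokw, kw, uw, ul, ubxii, ur, beta``.
    method : str
        One of the nine estimation methods (default maximum likelihood).
    n_starts : int or None
        Number of multi-start points (None = per-family default).
    random_state : int
        Seed for the Latin-hypercube starting points.

    Attributes (after fit)
    ----------------------
    params_ : ndarray of fitted parameters
    objective_ : objective value at the optimum
    neg2loglik_ : -2 log-likelihood at ``params_``
    se_ : standard errors (MLE only, may be None)
    converged_ : bool
    result_ : the full FitResult
    """

    def __init__(self, family="gmokw", method="mle", n_starts=None,
                 random_state=DEFAULT_SEED):
        self.family = family
        self.method = method
        self.n_starts = n_starts
        self.random_state = random_state

    def get_params(self, deep=True):
        return {"family": self.family, "method": self.method,
                "n_starts": self.n_starts, "random_state": self.random_state}

    def set_params(self, **kw):
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).ravel()
        res = fit(UnitSample(X), family=self.family, method=self.method,
                  n_starts=self.n_starts, seed=self.random_state)
        self.result_ = res
        self.params_ = res.params
        self.objective_ = res.objective
        self.neg2loglik_ = res.neg2loglik
        self.se_ = res.se
        self.converged_ = res.converged
        return self

    def score(self, X, y=None):
        """Mean log-likelihood of X under the fitted parameters."""
        fam = get_family(self.family)
        return float(np.mean(fam.logpdf(np.asarray(X, float).ravel(), self.params_)))

    def sample(self, n, seed=0):
        """Inverse-transform sample from the fitted distribution."""
        fam = get_family(self.family)
        if fam.ppf is None:
            raise NotImplementedError(f"no quantile function for {fam.name}")
        rng = np.random.default_rng(seed)
        return fam.ppf(rng.uniform(size=int(n)), self.params_)
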