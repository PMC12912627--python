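"""Competitor unit distributions: KW, UW, UL, UBXII, UR, Beta.

Each family is described by a small record holding its log-density, cdf,
parameter count/kinds (for the unconstrained optimization transforms),
an optional closed-form MLE, and a moment-flavoured starting value.

Densities (x in (0,1); alpha, lambda the family's own shapes):

    KW     a*l*x^(a-1)*(1-x^a)^(l-1)                 cdf 1-(1-x^a)^l
    UW     (1/x)*a*l*(-log x)^(l-1)*exp(-a(-log x)^l) cdf exp(-a(-log x)^l)
    UL     a^2/(1+a)*(1-x)^-3*exp(-a*x/(1-x))         cdf 1-(1+a*x/((1+a)(1-x)))*exp(-a*x/(1-x))
    UBXII  a*l*(-log x)^(l-1)*(1+(-log x)^l)^(-a-1)/x cdf (1+(-log x)^l)^(-a)
    UR     -2*a*log(x)/x*exp(-a*log^2 x)              cdf exp(-a*log^2 x)
    Beta   x^(a-1)(1-x)^(l-1)/B(a,l)                  (scipy.stats.beta)

The unit-Lindley display in the source literature carries a spurious
second symbol; it is a one-parameter family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .distributions import GMOKWParams, gmokw_cdf, gmokw_logpdf, gmokw_quantile

__all__ = ["FAMILIES", "Family", "family_logpdf", "family_cdf", "competitor_logpdf_cdf"]


def _neglog(x):
    return -np.log(np.asarray(x, dtype=float))


# ---------------------------------------------------------------- KW
def _kw_logpdf(x, p):
    a, l = p
    x = np.asarray(x, dtype=float)
    return np.log(a) + np.log(l) + (a - 1) * np.log(x) + (l - 1) * np.log1p(-(x**a))


def _kw_cdf(x, p):
    a, l = p
    x = np.asarray(x, dtype=float)
    return -np.expm1(l * np.log1p(-(x**a)))


def _kw_ppf(q, p):
    a, l = p
    q = np.asarray(q, dtype=float)
    return (-np.expm1(np.log1p(-q) / l)) ** (1.0 / a)


# ---------------------------------------------------------------- UW
def _uw_logpdf(x, p):
    a, l = p
    s = _neglog(x)
    return -np.log(np.asarray(x, float)) + np.log(a) + np.log(l) + (l - 1) * np.log(s) - a * s**l


def _uw_cdf(x, p):
    a, l = p
    return np.exp(-a * _neglog(x) ** l)


def _uw_ppf(q, p):
    a, l = p
    q = np.asarray(q, dtype=float)
    return np.exp(-((-np.log(q) / a) ** (1.0 / l)))


# ---------------------------------------------------------------- UL
def _ul_logpdf(x, p):
    (a,) = p
    x = np.asarray(x, dtype=float)
    r = x / (1.0 - x)
    return 2 * np.log(a) - np.log1p(a) - 3 * np.log1p(-x) - a * r


def _ul_cdf(x, p):
    (a,) = p
    x = np.asarray(x, dtype=float)
    r = x / (1.0 - x)
    return 1.0 - (1.0 + a * r / (1.0 + a)) * np.exp(-a * r)


def _ul_mle(y):
    """Stationarity of the UL log-likelihood gives a quadratic in alpha."""
    n = y.size
    s = np.sum(y / (1.0 - y))
    return (n - s + np.sqrt((n - s) ** 2 + 8.0 * n * s)) / (2.0 * s)


# ---------------------------------------------------------------- UBXII
def _ubxii_logpdf(x, p):
    a, l = p
    s = _neglog(x)
    return (
        np.log(a) + np.log(l) + (l - 1) * np.log(s)
        - (a + 1) * np.log1p(s**l) - np.log(np.asarray(x, float))
    )


def _ubxii_cdf(x, p):
    a, l = p
    return np.exp(-a * np.log1p(_neglog(x) ** l))


def _ubxii_ppf(q, p):
    a, l = p
    q = np.asarray(q, dtype=float)
    return np.exp(-((np.expm1(-np.log(q) / a)) ** (1.0 / l)))


# ---------------------------------------------------------------- UR
def _ur_logpdf(x, p):
    (a,) = p
    s = _neglog(x)
    return np.log(2.0) + np.log(a) + np.log(s) - np.log(np.asarray(x, float)) - a * s**2


def _ur_cdf(x, p):
    (a,) = p
    return np.exp(-a * _neglog(x) ** 2)


def _ur_ppf(q, p):
    (a,) = p
    q = np.asarray(q, dtype=float)
    return np.exp(-np.sqrt(-np.log(q) / a))


def _ur_mle(y):
    """alpha_hat = n / sum(log^2 y): closed form from the score equation."""
    return y.size / np.sum(np.log(y) ** 2)


# ---------------------------------------------------------------- Beta
def _beta_logpdf(x, p):
    a, l = p
    return stats.beta.logpdf(x, a, l)


def _beta_cdf(x, p):
    a, l = p
    return stats.beta.cdf(x, a, l)


def _beta_ppf(q, p):
    a, l = p
    return stats.beta.ppf(q, a, l)


def _beta_start(y):
    """Method-of-moments start for Beta shapes."""
    m, v = np.mean(y), np.var(y)
    v = min(v, m * (1 - m) * 0.999)
    c = m * (1 - m) / v - 1.0
    return np.array([max(m * c, 1e-3), max((1 - m) * c, 1e-3)])


# ---------------------------------------------------------------- GMOKW
def _gmokw_logpdf(x, p):
    return gmokw_logpdf(x, GMOKWParams(*p))


def _gmokw_cdf(x, p):
    return gmokw_cdf(x, GMOKWParams(*p))


def _gmokw_ppf(q, p):
    return gmokw_quantile(q, GMOKWParams(*p))


@dataclass(frozen=True)
class Family:
    name: str
    n_params: int
    kinds: tuple  # "unit" or "pos" per parameter, for optimization transforms
    logpdf: Callable
    cdf: Callable
    ppf: Optional[Callable] = None
    closed_form_mle: Optional[Callable] = None
    start: Optional[Callable] = None

    def validate(self, params):
        params = np.asarray(params, dtype=float)
        if params.size != self.n_params:
            raise ValueError(
                f"{self.name} takes {self.n_params} parameter(s), got {params.size}"
            )
        for v, kind in zip(params, self.kinds):
            if kind == "unit" and not (0.0 < v < 1.0):
                raise ValueError(f"{self.name}: parameter {v} outside (0,1)")
            if kind == "pos" and not v > 0.0:
                raise ValueError(f"{self.name}: parameter {v} must be positive")
        return params


def _two_shape_start(y):
    return np.array([1.0, 1.0])


FAMILIES = {
    "gmokw": Family("gmokw", 4, ("unit", "unit", "pos", "pos"),
                    _gmokw_logpdf, _gmokw_cdf, _gmokw_ppf),
    "kw": Family("kw", 2, ("pos", "pos"), _kw_logpdf, _kw_cdf, _kw_ppf,
                 start=_two_shape_start),
    "uw": Family("uw", 2, ("pos", "pos"), _uw_logpdf, _uw_cdf, _uw_ppf,
                 start=_two_shape_start),
    "ul": Family("ul", 1, ("pos",), _ul_logpdf, _ul_cdf, closed_form_mle=_ul_mle),
    "ubxii": Family("ubxii", 2, ("pos", "pos"), _ubxii_logpdf, _ubxii_cdf, _ubxii_ppf,
                    start=_two_shape_start),
    "ur": Family("ur", 1, ("pos",), _ur_logpdf, _ur_cdf, _ur_ppf,
                 closed_form_mle=_ur_mle),
    "beta": Family("beta", 2, ("pos", "pos"), _beta_logpdf, _beta_cdf, _beta_ppf,
                   start=_beta_start),
}


def get_family(name: str) -> Family:
    key = str(name).lower()
    if key not in FAMILIES:
        raise ValueError(f"unknown family {name!r}; choose from {sorted(FAMILIES)}")
    return FAMILIES[key]


def family_logpdf(name, x, params):
    fam = get_family(name)
    return fam.logpdf(x, fam.validate(params))


def family_cdf(name, x, params):
    fam = get_family(name)
    return fam.cdf(x, fam.validate(params))


def competitor_logpdf_cdf(name, x, params):
    """(log-density, cdf) pair for one of the six competitor families."""
    fam = get_family(name)
    p = fam.validate(params)
    return fam.logpdf(x, p), fam.cdf(x, p)
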