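"""Goodness-of-fit statistics, approximate p-values, and model selection.

EDF statistics at a fitted cdf F (order statistics y_(1) <= ... <= y_(n),
F_i = F(y_(i))):

    KS  = max_i max(i/n - F_i, F_i - (i-1)/n)
    AD  = -n - (1/n) sum (2i-1) [log F_i + log(1 - F_{n+1-i})]
    CvM = 1/(12n) + sum (F_i - (2i-1)/(2n))^2

P-values use the classical all-parameters-known asymptotics: the
Kolmogorov series for KS, the Marsaglia & Marsaglia (2004) 'adinf'
approximation for AD, and the Anderson-Darling (1952) Bessel-K series for
the CvM limit.  These are approximations — the null here has estimated
parameters, so the reported p-values are conventional summaries, not
exact test levels.

Information criteria from -2 log-likelihood, parameter count k, size n:

    AIC  = -2logL + 2k            BIC  = -2logL + k log n
    CAIC = AIC + 2k(k+1)/(n-k-1)  HQIC = -2logL + 2k log(log n)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special

from .competitors import get_family
from .distributions import UnitSample
from .estimators import FitResult, fit

__all__ = ["GoFReport", "edf_statistics", "gof_pvalues", "information_criteria",
           "gof_report", "compare_models", "TABLE_COLUMNS"]

TABLE_COLUMNS = ["-2logL", "AIC", "BIC", "CAIC", "HQIC", "KS", "AD", "CvM",
                 "p(KS)", "p(AD)", "p(CvM)"]


def _as_sample(sample) -> UnitSample:
    return sample if isinstance(sample, UnitSample) else UnitSample(np.asarray(sample))


def edf_statistics(sample, cdf):
    """(KS, AD, CvM) of the sample against a fitted cdf callable."""
    s = _as_sample(sample)
    n = s.n
    F = np.asarray(cdf(s.sorted_values), dtype=float)
    if np.any((F < -1e-9) | (F > 1 + 1e-9)):
        raise ValueError("cdf values outside [0,1]")
    i = np.arange(1, n + 1)
    ks = float(np.max(np.maximum(i / n - F, F - (i - 1) / n)))
    Fc = np.clip(F, 1e-12, 1 - 1e-12)
    if np.any(F != Fc):
        import warnings

        warnings.warn("cdf values at 0/1 clipped to 1e-12 for AD", RuntimeWarning)
    ad = float(-n - np.sum((2 * i - 1) * (np.log(Fc) + np.log1p(-Fc[n - i]))) / n)
    cvm = float(1.0 / (12 * n) + np.sum((Fc - (2 * i - 1) / (2 * n)) ** 2))
    return ks, ad, cvm


def _ad_sf(z):
    """Upper tail of the asymptotic AD distribution (Marsaglia & Marsaglia 2004)."""
    z = float(z)
    if z <= 0:
        return 1.0
    if z < 2.0:
        cdf = (
            np.exp(-1.2337141 / z) / np.sqrt(z)
            * (2.00012 + (0.247105 - (0.0649821 - (0.0347962
               - (0.0116720 - 0.00168691 * z) * z) * z) * z) * z)
        )
    else:
        cdf = np.exp(-np.exp(1.0776 - (2.30695 - (0.43424 - (0.082433
                     - (0.008056 - 0.0003146 * z) * z) * z) * z) * z))
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def _cvm_sf(x, n_terms=8):
    """Upper tail of the asymptotic CvM distribution (Anderson-Darling 1952).

    cdf(x) = (1/(pi sqrt(x))) sum_j (-1)^j C(-1/2, j) sqrt(4j+1)
             exp(-(4j+1)^2/(16x)) K_{1/4}((4j+1)^2/(16x))
    """
    x = float(x)
    if x <= 0:
        return 1.0
    total = 0.0
    for j in range(n_terms):
        c = special.binom(-0.5, j) * (-1.0) ** j
        a = (4 * j + 1) ** 2 / (16.0 * x)
        if a > 700:
            continue
        total += c * np.sqrt(4 * j + 1) * np.exp(-a) * special.kv(0.25, a)
    cdf = total / (np.pi * np.sqrt(x))
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def gof_pvalues(ks, ad, cvm, n):
    """Approximate p-values for the three EDF statistics (simple-null asymptotics)."""
    p_ks = float(np.clip(special.kolmogorov(np.sqrt(n) * ks), 0.0, 1.0))
    return p_ks, _ad_sf(ad), _cvm_sf(cvm)


def information_criteria(neg2loglik, k, n):
    """(AIC, BIC, CAIC, HQIC) from -2 log-likelihood, k parameters, n points."""
    if k > 0 and n <= k + 1:
        raise ValueError("CAIC undefined for n <= k+1")
    aic = neg2loglik + 2.0 * k
    bic = neg2loglik + k * np.log(n)
    caic = aic + (2.0 * k * (k + 1)) / (n - k - 1) if k else aic
    hqic = neg2loglik + 2.0 * k * np.log(np.log(n))
    return aic, bic, caic, hqic


@dataclass
class GoFReport:
    """One row of a model-comparison table."""

    family: str
    params: np.ndarray
    neg2loglik: float
    aic: float
    bic: float
    caic: float
    hqic: float
    ks: float
    ad: float
    cvm: float
    p_ks: float
    p_ad: float
    p_cvm: float
    k: int
    n: int
    converged: bool = True

    def as_row(self):
        return {"-2logL": self.neg2loglik, "AIC": self.aic, "BIC": self.bic,
                "CAIC": self.caic, "HQIC": self.hqic, "KS": self.ks, "AD": self.ad,
                "CvM": self.cvm, "p(KS)": self.p_ks, "p(AD)": self.p_ad,
                "p(CvM)": self.p_cvm}


def gof_report(sample, family, fit_result: Optional[FitResult] = None,
               method="mle", n_starts=None, seed=20240101) -> GoFReport:
    """Fit (unless a FitResult is supplied) and compute the full GoF row."""
    s = _as_sample(sample)
    fam = get_family(family)
    res = fit_result if fit_result is not None else fit(
        s, family=fam.name, method=method, n_starts=n_starts, seed=seed)
    params = res.params
    ks, ad, cvm = edf_statistics(s, lambda y: fam.cdf(y, params))
    p_ks, p_ad, p_cvm = gof_pvalues(ks, ad, cvm, s.n)
    n2l = res.neg2loglik
    aic, bic, caic, hqic = information_criteria(n2l, fam.n_params, s.n)
    return GoFReport(fam.name, params, n2l, aic, bic, caic, hqic,
                     ks, ad, cvm, p_ks, p_ad, p_cvm, fam.n_params, s.n,
                     res.converged)


def compare_models(sample, families=None, method="mle", seed=20240101,
                   n_starts=None, sort_by="AIC") -> pd.DataFrame:
    """Fit several families and rank them (lowest AIC first by default).

    A family whose fit fails is kept in the table with NaN cells rather
    than silently dropped.
    """
    s = _as_sample(sample)
    if families is None:
        families = ["gmokw", "kw", "uw", "ul", "ubxii", "ur", "beta"]
    rows, index, fitted = [], [], {}
    for name in families:
        try:
            rep = gof_report(s, name, method=method, seed=seed, n_starts=n_starts)
            rows.append(rep.as_row())
            fitted[name] = rep
        except Exception as exc:  # report failures, never drop them
            rows.append({c: np.nan for c in TABLE_COLUMNS})
            fitted[name] = exc
        index.append(get_family(name).name)
    df = pd.DataFrame(rows, index=index, columns=TABLE_COLUMNS)
    df.attrs["reports"] = fitted
    if sort_by:
        df = df.sort_values(sort_by, na_position="last")
    return df
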