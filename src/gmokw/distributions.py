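"""The generalized Marshall-Olkin Kumaraswamy (GMOKW) distribution on (0,1).

The GMOKW distribution arises by passing the Kumaraswamy baseline
G(y) = 1 - (1 - y^kappa)^gamma through the two-parameter generalized
Marshall-Olkin ratio transform

    F(y) = [lambda*z + (1 - lambda)*z^2] / [alpha + (1 - alpha)*z],
    z = 1 - (1 - y^kappa)^gamma,

with tilt parameters alpha, lambda in (0,1) and Kumaraswamy shapes
kappa, gamma > 0.  When alpha == lambda the ratio collapses and the
distribution reduces exactly to Kumaraswamy(kappa, gamma).

All densities are computed on the log scale; z is evaluated through
expm1/log1p so that extreme shape values do not lose precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.special import gammaln

__all__ = [
    "GMOKWParams",
    "UnitSample",
    "MomentReport",
    "gmokw_logpdf",
    "gmokw_pdf",
    "gmokw_cdf",
    "gmokw_sf",
    "gmokw_quantile",
    "gmokw_rng",
    "gmokw_hazard",
    "gmokw_moments",
    "incomplete_moment",
    "lorenz_bonferroni",
    "series_pdf",
    "series_moment",
]


@dataclass(frozen=True)
class GMOKWParams:
    """Parameter quadruple (alpha, lam, kappa, gamma).

    alpha, lam are the Marshall-Olkin tilt parameters, strictly inside
    (0,1); kappa, gamma are the positive Kumaraswamy shapes.  Boundary
    values are rejected: the family is defined on the open region.
    """

    alpha: float
    lam: float
    kappa: float
    gamma: float

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie strictly in (0,1), got {self.alpha}")
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"lambda must lie strictly in (0,1), got {self.lam}")
        if not (self.kappa > 0.0 and np.isfinite(self.kappa)):
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if not (self.gamma > 0.0 and np.isfinite(self.gamma)):
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.lam, self.kappa, self.gamma])


def _unpack(params):
    if isinstance(params, GMOKWParams):
        return params.alpha, params.lam, params.kappa, params.gamma
    a, l, k, g = params
    return a, l, k, g


@dataclass
class UnitSample:
    """A univariate sample strictly inside (0,1), with cached order statistics."""

    values: np.ndarray
    sorted_values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1:
            raise ValueError("sample must contain at least one observation")
        if not np.all(np.isfinite(v)):
            raise ValueError("sample contains non-finite values")
        bad = (v <= 0.0) | (v >= 1.0)
        if np.any(bad):
            rows = np.nonzero(bad)[0]
            raise ValueError(
                f"values must lie strictly in (0,1); offending rows {rows[:10].tolist()} "
                f"with values {v[rows[:10]].tolist()}"
            )
        self.values = v
        self.sorted_values = np.sort(v)

    @property
    def n(self) -> int:
        return self.values.size


def _z_and_logs(y, kappa, gamma):
    """Return (z, log_w, log_y, log1m_t) with w = (1-y^kappa)^gamma, z = 1-w."""
    log_y = np.log(y)
    t = np.exp(kappa * log_y)  # y^kappa in (0,1)
    log1m_t = np.log1p(-t)
    log_w = gamma * log1m_t
    z = -np.expm1(log_w)
    return z, log_w, log_y, log1m_t


def gmokw_logpdf(y, params):
    """Log-density of GMOKW at y; -inf outside the open support."""
    alpha, lam, kappa, gamma = _unpack(params)
    y = np.asarray(y, dtype=float)
    inside = (y > 0.0) & (y < 1.0)
    yy = np.where(inside, y, 0.5)
    z, _, log_y, log1m_t = _z_and_logs(yy, kappa, gamma)
    num = (1.0 - alpha) * (1.0 - lam) * z * z + 2.0 * alpha * (1.0 - lam) * z + alpha * lam
    den = alpha + (1.0 - alpha) * z
    logpdf = (
        np.log(num)
        - 2.0 * np.log(den)
        + np.log(kappa) + np.log(gamma)
        + (kappa - 1.0) * log_y
        + (gamma - 1.0) * log1m_t
    )
    out = np.where(inside, logpdf, -np.inf)
    return out if out.ndim else float(out)


def gmokw_pdf(y, params, strict=False):
    """GMOKW density; zero outside (0,1) unless strict=True (then raises)."""
    if strict:
        y_arr = np.asarray(y, dtype=float)
        if np.any((y_arr <= 0.0) | (y_arr >= 1.0)):
            raise ValueError("y outside the open support (0,1)")
    out = np.exp(gmokw_logpdf(y, params))
    return out if np.ndim(out) else float(out)


def gmokw_cdf(y, params):
    """GMOKW cumulative distribution function, clamped to [0,1]."""
    alpha, lam, kappa, gamma = _unpack(params)
    y = np.asarray(y, dtype=float)
    below, above = y <= 0.0, y >= 1.0
    yy = np.clip(y, 1e-300, 1.0 - 1e-16)
    z, _, _, _ = _z_and_logs(yy, kappa, gamma)
    F = (lam * z + (1.0 - lam) * z * z) / (alpha + (1.0 - alpha) * z)
    F = np.clip(F, 0.0, 1.0)
    F = np.where(below, 0.0, np.where(above, 1.0, F))
    return F if F.ndim else float(F)


def gmokw_sf(y, params):
    """Survival function 1-F, computed through the factorized complement.

    The complement factorizes as (1-z)(alpha + (1-lambda) z) over the same
    denominator, which keeps precision as y -> 1.
    """
    alpha, lam, kappa, gamma = _unpack(params)
    y = np.asarray(y, dtype=float)
    below, above = y <= 0.0, y >= 1.0
    yy = np.clip(y, 1e-300, 1.0 - 1e-16)
    z, log_w, _, _ = _z_and_logs(yy, kappa, gamma)
    sf = np.exp(log_w) * (alpha + (1.0 - lam) * z) / (alpha + (1.0 - alpha) * z)
    sf = np.where(below, 1.0, np.where(above, 0.0, sf))
    return sf if sf.ndim else float(sf)


def _z_root(p, alpha, lam):
    """Root z in [0,1] of (1-lambda) z^2 + (lambda - p(1-alpha)) z - p*alpha = 0.

    This inverts the Marshall-Olkin ratio F(z)=p.  The two real roots have
    opposite signs; the positive one is returned, through the form that
    avoids cancellation when the linear coefficient is positive.
    """
    p = np.asarray(p, dtype=float)
    a = 1.0 - lam
    b = lam - p * (1.0 - alpha)
    c = -p * alpha
    disc = np.sqrt(b * b - 4.0 * a * c)
    # b > 0: z = 2*p*alpha/(b + disc) is exact as a -> 0 (lambda -> 1 limit)
    z = np.where(b > 0.0, -2.0 * c / (b + disc), (-b + disc) / (2.0 * a))
    return np.clip(z, 0.0, 1.0)


def gmokw_quantile(p, params):
    """Analytic quantile function Q(p).

    Solves the quadratic in z = 1-(1-y^kappa)^gamma, then inverts the
    Kumaraswamy transform: y = (1 - (1-z)^(1/gamma))^(1/kappa).
    """
    alpha, lam, kappa, gamma = _unpack(params)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p must lie in [0,1]")
    z = _z_root(p, alpha, lam)
    with np.errstate(divide="ignore", invalid="ignore"):
        # y = (1 - (1-z)^(1/gamma))^(1/kappa) via nested log1p/expm1
        log_w = np.log1p(-z) / gamma      # log (1-z)^(1/gamma)
        log_t = np.log(-np.expm1(log_w))  # log (1 - (1-z)^(1/gamma))
        y = np.exp(log_t / kappa)
    y = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, y))
    return y if y.ndim else float(y)


def gmokw_rng(n, params, seed):
    """Inverse-transform sample of size n; identical seed, identical sample."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=int(n))
    return UnitSample(gmokw_quantile(u, params))


def gmokw_hazard(y, params):
    """Hazard rate f/(1-F), evaluated on the log scale to survive y -> 1."""
    alpha, lam, kappa, gamma = _unpack(params)
    y = np.asarray(y, dtype=float)
    yy = np.clip(y, 1e-300, 1.0 - 1e-16)
    z, log_w, log_y, log1m_t = _z_and_logs(yy, kappa, gamma)
    num = (1.0 - alpha) * (1.0 - lam) * z * z + 2.0 * alpha * (1.0 - lam) * z + alpha * lam
    log_f = (
        np.log(num)
        - 2.0 * np.log(alpha + (1.0 - alpha) * z)
        + np.log(kappa) + np.log(gamma)
        + (kappa - 1.0) * log_y
        + (gamma - 1.0) * log1m_t
    )
    log_sf = log_w + np.log(alpha + (1.0 - lam) * z) - np.log(alpha + (1.0 - alpha) * z)
    h = np.exp(log_f - log_sf)
    return h if h.ndim else float(h)


@dataclass
class MomentReport:
    """Raw moments, central summaries, and optional incomplete moments."""

    raw_moments: np.ndarray
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    incomplete: np.ndarray | None = None

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.kurtosis < self.skewness**2 + 1 - 1e-8:
            raise ValueError("moment inequality K >= S^2 + 1 violated: inconsistent input")


def _raw_moment(r, params):
    """E[Y^r] = integral of Q(u)^r du over (0,1): a bounded, smooth integrand."""
    val, err = integrate.quad(
        lambda u: gmokw_quantile(u, params) ** r, 0.0, 1.0, limit=200, epsabs=1e-12
    )
    return val


def gmokw_moments(params, r_max=4, upper=None):
    """Moment summary: raw moments to order r_max, S and K, incomplete moments.

    Moments are obtained by adaptive quadrature in quantile space
    (E[Y^r] = int_0^1 Q(u)^r du), which avoids the density's possible
    endpoint singularities.  Skewness/kurtosis use the standard
    central-moment formulas.
    """
    _unpack(params)  # validate
    if r_max < 2:
        r_max = 4
    m = np.array([_raw_moment(r, params) for r in range(1, max(r_max, 4) + 1)])
    m1, m2, m3, m4 = m[:4]
    var = m2 - m1 * m1
    sd3 = var ** 1.5
    S = (m3 - 3 * m1 * m2 + 2 * m1**3) / sd3
    K = (m4 - 4 * m1 * m3 + 6 * m2 * m1**2 - 3 * m1**4) / var**2
    inc = None
    if upper is not None:
        inc = np.array([incomplete_moment(r, upper, params) for r in range(1, r_max + 1)])
    return MomentReport(m[:r_max], float(m1), float(var), float(S), float(K), inc)


def incomplete_moment(r, upper, params):
    """r-th incomplete moment int_0^upper y^r f(y) dy, via quantile space."""
    p_up = gmokw_cdf(upper, params)
    val, err = integrate.quad(
        lambda u: gmokw_quantile(u, params) ** r, 0.0, p_up, limit=200, epsabs=1e-12
    )
    return val


def series_moment(r, params, k_max=400):
    """Gamma-function series for E[Y^r] (truncated); quadrature is authoritative.

    Resummed form of the binomial expansion: with B_j = B(r/kappa + 1, gamma*j),

        E[Y^r] = gamma*B_1' + (lambda-alpha)*gamma *
                 sum_k (1-alpha)^k [(k+2) B_{k+2} - (k+1) B_{k+1}],

    where B_1' = B(r/kappa + 1, gamma).  The inner alternating binomial sums
    of the term-by-term display cancel catastrophically for large k; this
    collapsed series is their exact resummation and converges geometrically
    in (1-alpha).
    """
    alpha, lam, kappa, gamma = _unpack(params)

    def betaf(j):
        return np.exp(
            gammaln(r / kappa + 1.0) + gammaln(gamma * j) - gammaln(r / kappa + gamma * j + 1.0)
        )

    k = np.arange(0, k_max + 1)
    Bk1 = betaf(k + 1.0)
    Bk2 = betaf(k + 2.0)
    lead = gamma * betaf(1.0)
    corr = (lam - alpha) * gamma * np.sum((1.0 - alpha) ** k * ((k + 2) * Bk2 - (k + 1) * Bk1))
    return float(lead + corr)


def lorenz_bonferroni(p, params):
    """Lorenz curve L(p) and Bonferroni curve B(p) = L(p)/p.

    L(p) is the normalized first incomplete moment up to the p-th quantile:
    L(p) = (1/mu) * int_0^p Q(u) du.
    """
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0,1)")
    mu = _raw_moment(1, params)
    val, err = integrate.quad(
        lambda u: gmokw_quantile(u, params), 0.0, p, limit=200, epsabs=1e-12
    )
    L = val / mu
    return L, L / p


def series_pdf(y, params, k_max=200):
    """Series-expansion approximation of the GMOKW density.

    f(y) = g(y) + sum_k (lambda-alpha)(1-alpha)^k * inner_k(y), where the
    inner binomial sum over m of C(k+1,m)(-1)^m (m+1) G^m collapses to
    (1-G)^k (1 - (k+2) G) -- the collapsed form is used because the raw
    alternating binomial sum cancels catastrophically for large k.
    Converges to gmokw_pdf as k_max grows (slowly for y near 0).
    """
    alpha, lam, kappa, gamma = _unpack(params)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    y = np.asarray(y, dtype=float)
    z, log_w, log_y, log1m_t = _z_and_logs(y, kappa, gamma)
    G = z
    g = np.exp(np.log(kappa) + np.log(gamma) + (kappa - 1) * log_y + (gamma - 1) * log1m_t)
    k = np.arange(0, k_max + 1)
    # outer terms: (lam-alpha)(1-alpha)^k (1-G)^k (1-(k+2)G) * g, vectorized over k
    Gc = np.atleast_1d(G)[..., None]
    terms = (lam - alpha) * ((1.0 - alpha) * (1.0 - Gc)) ** k * (1.0 - (k + 2) * Gc)
    total = np.atleast_1d(g) + terms.sum(axis=-1) * np.atleast_1d(g)
    return total if np.ndim(y) else float(total[0])
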