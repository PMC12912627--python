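"""Core GMOKW distribution functions: hand values, oracles, invariants."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from gmokw.distributions import (
    GMOKWParams,
    UnitSample,
    gmokw_cdf,
    gmokw_hazard,
    gmokw_logpdf,
    gmokw_moments,
    gmokw_pdf,
    gmokw_quantile,
    gmokw_rng,
    gmokw_sf,
    lorenz_bonferroni,
    series_moment,
    series_pdf,
)

UNIFORM = GMOKWParams(0.3, 0.3, 1, 1)     # alpha=lambda, KW(1,1): the uniform law
TILTED = GMOKWParams(0.5, 0.2, 1, 1)      # hand-computable tilt of the uniform


class TestParameterValidation:
    @pytest.mark.parametrize("bad", [
        dict(alpha=0.0), dict(alpha=1.0), dict(lam=0.0), dict(lam=1.0),
        dict(kappa=0.0), dict(kappa=-1.0), dict(gamma=0.0), dict(gamma=np.inf),
    ])
    def test_boundary_parameters_rejected(self, bad):
        kw = dict(alpha=0.3, lam=0.4, kappa=1.0, gamma=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            GMOKWParams(**kw)

    def test_sample_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="strictly in"):
            UnitSample(np.array([0.2, 1.0, 0.5]))
        with pytest.raises(ValueError, match="strictly in"):
            UnitSample(np.array([0.0]))


class TestPointValues:
    """Hand-derived evaluations of pdf/cdf/quantile/hazard."""

    def test_uniform_collapse(self):
        assert gmokw_pdf(0.5, UNIFORM) == pytest.approx(1.0, abs=1e-12)
        assert gmokw_cdf(0.5, UNIFORM) == pytest.approx(0.5, abs=1e-12)
        assert gmokw_quantile(0.5, UNIFORM) == pytest.approx(0.5, abs=1e-12)
        assert gmokw_hazard(0.5, UNIFORM) == pytest.approx(2.0, abs=1e-10)

    def test_tilted_hand_values(self):
        # z = 0.5: numerator 0.6, denominator 0.75^2, kernel 1
        assert gmokw_pdf(0.5, TILTED) == pytest.approx(16 / 15, abs=1e-12)
        assert gmokw_cdf(0.5, TILTED) == pytest.approx(0.4, abs=1e-12)
        assert gmokw_quantile(0.4, TILTED) == pytest.approx(0.5, abs=1e-12)
        assert gmokw_hazard(0.5, TILTED) == pytest.approx((16 / 15) / 0.6, rel=1e-10)

    def test_support_conventions(self):
        assert gmokw_pdf(-0.1, TILTED) == 0.0
        assert gmokw_pdf(1.2, TILTED) == 0.0
        assert gmokw_logpdf(0.0, TILTED) == -np.inf
        assert gmokw_cdf(0.0, TILTED) == 0.0
        assert gmokw_cdf(1.0, TILTED) == 1.0
        assert gmokw_quantile(0.0, TILTED) == 0.0
        assert gmokw_quantile(1.0, TILTED) == 1.0
        with pytest.raises(ValueError):
            gmokw_quantile(1.5, TILTED)
        with pytest.raises(ValueError):
            gmokw_pdf(1.5, TILTED, strict=True)


class TestNormalizationAndConsistency:
    def test_density_integrates_to_one(self, random_params):
        for p in random_params[:5]:
            val, err = integrate.quad(lambda y: gmokw_pdf(y, p), 0, 1, limit=200)
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_cdf_derivative_matches_pdf(self, random_params):
        rng = np.random.default_rng(7)
        for p in random_params[:4]:
            y = rng.uniform(0.05, 0.95, 5)
            h = 1e-6
            fd = (gmokw_cdf(y + h, p) - gmokw_cdf(y - h, p)) / (2 * h)
            assert np.allclose(fd, gmokw_pdf(y, p), rtol=1e-5)

    def test_sf_complements_cdf(self, random_params):
        y = np.linspace(0.01, 0.99, 21)
        for p in random_params[:4]:
            assert np.allclose(gmokw_sf(y, p) + gmokw_cdf(y, p), 1.0, atol=1e-12)

    def test_hazard_identity(self, random_params):
        # h(y) (1 - F(y)) = f(y)
        rng = np.random.default_rng(11)
        y = rng.uniform(0.02, 0.98, 50)
        for p in random_params[:3]:
            lhs = gmokw_hazard(y, p) * gmokw_sf(y, p)
            assert np.allclose(lhs, gmokw_pdf(y, p), atol=1e-10)


class TestKumaraswamyReduction:
    """alpha == lambda collapses the tilt: GMOKW = KW(kappa, gamma) exactly."""

    @pytest.mark.parametrize("a", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("kg", [(2.0, 3.0), (0.5, 0.75)])
    def test_cdf_pointwise(self, a, kg):
        k, g = kg
        y = np.linspace(0.01, 0.99, 99)
        kw_cdf = -np.expm1(g * np.log1p(-(y**k)))
        assert np.max(np.abs(gmokw_cdf(y, GMOKWParams(a, a, k, g)) - kw_cdf)) <= 1e-12

    def test_mean_closed_form(self):
        # KW(kappa, gamma) mean: gamma * B(1 + 1/kappa, gamma)
        m = gmokw_moments(GMOKWParams(0.3, 0.3, 0.5, 0.75))
        assert m.mean == pytest.approx(0.75 * special.beta(3, 0.75), abs=1e-8)


class TestQuantile:
    def test_round_trip_at_model_draws(self, random_params):
        # y drawn from the model itself, where the density is appreciable
        rng = np.random.default_rng(3)
        worst = 0.0
        for p in random_params:
            u = rng.uniform(0.01, 0.99, 10)
            y = gmokw_quantile(u, p)
            worst = max(worst, np.max(np.abs(gmokw_quantile(gmokw_cdf(y, p), p) - y)))
        assert worst <= 1e-9

    def test_against_bisection_oracle(self, random_params):
        from scipy.optimize import brentq

        for p in random_params[:4]:
            for q in (0.1, 0.5, 0.9):
                oracle = brentq(lambda y: gmokw_cdf(y, p) - q, 1e-12, 1 - 1e-12,
                                xtol=1e-14)
                assert gmokw_quantile(q, p) == pytest.approx(oracle, abs=1e-9)

    def test_lambda_near_one_limit(self):
        # quadratic degenerates; the stable branch must still invert the cdf
        p = GMOKWParams(0.3, 1 - 1e-12, 2.0, 3.0)
        q = gmokw_quantile(0.7, p)
        assert gmokw_cdf(q, p) == pytest.approx(0.7, abs=1e-9)


class TestSampling:
    def test_seed_determinism(self):
        a = gmokw_rng(100, TILTED, seed=42).values
        b = gmokw_rng(100, TILTED, seed=42).values
        assert np.array_equal(a, b)

    def test_ks_against_model_cdf(self):
        p = GMOKWParams(0.25, 0.5, 1.2, 1.5)
        s = gmokw_rng(5000, p, seed=99)
        res = stats.kstest(s.values, lambda y: gmokw_cdf(y, p))
        assert res.pvalue > 0.01

    def test_reduction_sample_mean(self):
        # KW(2,3) mean is 3 B(1.5, 3)
        s = gmokw_rng(5000, GMOKWParams(0.3, 0.3, 2, 3), seed=5)
        mean = 3 * special.beta(1.5, 3)
        m2 = 3 * special.beta(2, 3)
        se = np.sqrt((m2 - mean**2) / 5000)
        assert abs(s.values.mean() - mean) < 3 * se


class TestMoments:
    def test_uniform_moments(self):
        m = gmokw_moments(UNIFORM)
        assert m.mean == pytest.approx(0.5, abs=1e-9)
        assert m.variance == pytest.approx(1 / 12, abs=1e-9)

    def test_tabulated_mean_variance(self):
        # an independently quadrature-checked (E, V) reference point
        m = gmokw_moments(GMOKWParams(0.1, 0.2, 0.5, 0.75))
        assert m.mean == pytest.approx(0.3804, abs=5e-5)
        assert m.variance == pytest.approx(0.1094, abs=5e-5)

    def test_moment_inequality_holds(self, random_params):
        for p in random_params[:5]:
            m = gmokw_moments(p)
            assert m.kurtosis >= m.skewness**2 + 1 - 1e-8

    def test_series_matches_quadrature(self, random_params):
        for p in random_params[:5]:
            for r in (1, 2):
                quad = integrate.quad(lambda u: gmokw_quantile(u, p) ** r, 0, 1,
                                      limit=200)[0]
                assert series_moment(r, p, k_max=3000) == pytest.approx(quad, abs=1e-5)

    def test_incomplete_moment_is_mean_at_full_range(self):
        from gmokw.distributions import incomplete_moment

        p = GMOKWParams(0.4, 0.6, 2.0, 1.5)
        full = incomplete_moment(1, 1 - 1e-12, p)
        assert full == pytest.approx(gmokw_moments(p).mean, abs=1e-8)


class TestLorenzBonferroni:
    def test_uniform_hand_value(self):
        L, B = lorenz_bonferroni(0.5, UNIFORM)
        assert L == pytest.approx(0.25, abs=1e-9)
        assert B == pytest.approx(0.5, abs=1e-9)

    def test_normalization_limit(self):
        L, _ = lorenz_bonferroni(1 - 1e-9, TILTED)
        assert L == pytest.approx(1.0, abs=1e-6)

    def test_lorenz_properties(self, random_params):
        # L(p) <= p, non-decreasing, convex on a grid
        grid = np.linspace(0.01, 0.99, 99)
        for p in random_params[:3]:
            L = np.array([lorenz_bonferroni(q, p)[0] for q in grid])
            assert np.all(L <= grid + 1e-9)
            assert np.all(np.diff(L) >= -1e-12)
            assert np.all(np.diff(L, 2) >= -1e-9)


class TestSeriesPdf:
    def test_collapse_when_alpha_equals_lambda(self):
        y = np.linspace(0.05, 0.95, 7)
        p = GMOKWParams(0.4, 0.4, 2.0, 3.0)
        assert np.allclose(series_pdf(y, p, k_max=1), gmokw_pdf(y, p), atol=1e-14)

    def test_hand_value_at_tilted_point(self):
        assert series_pdf(0.5, TILTED, k_max=60) == pytest.approx(16 / 15, abs=1e-8)

    def test_matches_direct_pdf(self, random_params):
        rng = np.random.default_rng(13)
        for p in random_params[:5]:
            y = rng.uniform(0.15, 0.95, 10)  # small y converges slowly
            assert np.max(np.abs(series_pdf(y, p, k_max=4000) - gmokw_pdf(y, p))) <= 1e-6
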