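import numpy as np
import pytest
from scipy import integrate, stats

import omegaperf as op
from omegaperf.distribution import _moments_closed
from omegaperf.errors import DomainError, InvalidParameterError

from conftest import random_valid_params


class TestDensityAndDistribution:
    def test_invalid_parameters_raise(self):
        for bad in [(-1, 1, 1), (1, 0, 1), (1, 1, -2), (np.nan, 1, 1)]:
            with pytest.raises(InvalidParameterError):
                op.OmegaParams(*bad)

    def test_pdf_vanishes_at_origin_for_beta_above_one(self, running_params):
        assert op.pdf(1e-12, running_params) < 1e-9
        assert op.pdf(0.0, running_params) == 0.0

    def test_pdf_zero_outside_support(self, running_params):
        g = running_params.gamma_
        assert op.pdf(-1.0, running_params) == 0.0
        assert op.pdf(g + 1.0, running_params) == 0.0
        assert op.cdf(-1.0, running_params) == 0.0
        assert op.cdf(0.0, running_params) == 0.0
        assert op.cdf(g, running_params) == 1.0
        assert op.survival(0.0, running_params) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_normalization_random_params(self, seed):
        """Integral of the density over the support is 1 (quadrature oracle).

        Parameters span beta in [0.3, 5] and survival exponent in [1, 1e6].
        """
        params = random_valid_params(np.random.default_rng(seed))
        pts = [float(op.quantile(u, params)) for u in (1e-9, 0.5, 1 - 1e-9)]
        total, err = integrate.quad(
            lambda x: op.pdf(x, params), 0.0, params.gamma_, limit=300, points=pts
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_survival_complements_cdf(self, running_params):
        x = np.linspace(0.01, 50.0, 40)
        np.testing.assert_allclose(
            op.survival(x, running_params) + op.cdf(x, running_params),
            1.0, atol=1e-12,
        )

    def test_cdf_nondecreasing(self, synth_params):
        x = np.linspace(1e-6, synth_params.gamma_ - 1e-6, 500)
        assert np.all(np.diff(op.cdf(x, synth_params)) >= 0.0)

    def test_cdf_at_one_sigma_below_mean_matches_table(self, running_params):
        # survival at mu - sigma is the tabulated conforming rate 0.83213
        s = op.moments(running_params)
        assert op.cdf(s.mu - s.sigma, running_params) == pytest.approx(
            1.0 - 0.83213, abs=5e-4
        )

    def test_log_survival_at_one_sigma_above_mean(self, running_params):
        # the C_L = -1 table cell: survival 0.16438 at mu + sigma
        s = op.moments(running_params)
        assert op.log_survival(s.mu + s.sigma, running_params) == pytest.approx(
            np.log(0.16438), rel=1e-3
        )


class TestHazard:
    def test_hazard_equals_pdf_over_survival(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            params = random_valid_params(rng)
            x = float(op.quantile(rng.uniform(0.05, 0.95), params))
            assert op.hazard(x, params) == pytest.approx(
                op.pdf(x, params) / op.survival(x, params), rel=1e-10
            )

    def test_bathtub_shape_for_small_beta(self):
        """For beta < 1 the hazard decreases then increases: one sign change."""
        params = op.OmegaParams(1.0, 0.5, 10.0)
        x = np.linspace(1e-4, params.gamma_ * (1 - 1e-6), 4000)
        h = op.hazard(x, params)
        signs = np.sign(np.diff(h))
        changes = np.sum(np.diff(signs[signs != 0]) != 0)
        assert changes == 1
        assert signs[0] < 0 and signs[-1] > 0

    def test_hazard_diverges_at_endpoint(self, synth_params):
        g = synth_params.gamma_
        x = g * (1.0 - np.array([1e-6, 1e-8, 1e-10, 1e-12]))
        h = op.hazard(x, synth_params)
        assert np.all(np.diff(h) > 0.0)
        assert h[-1] > 1e8

    def test_hazard_raises_off_support(self, synth_params):
        with pytest.raises(DomainError):
            op.hazard(0.0, synth_params)
        with pytest.raises(DomainError):
            op.hazard(synth_params.gamma_, synth_params)


class TestQuantile:
    def test_round_trip_identities(self, running_params):
        u = np.array([1e-8, 0.1, 0.5, 0.9, 1 - 1e-8])
        x = op.quantile(u, running_params)
        np.testing.assert_allclose(op.cdf(x, running_params), u, rtol=1e-9)
        xs = np.asarray(op.quantile(np.linspace(1e-6, 1 - 1e-6, 20), running_params))
        np.testing.assert_allclose(
            op.quantile(op.cdf(xs, running_params), running_params), xs, rtol=1e-9
        )

    def test_endpoint_limits(self, synth_params):
        assert op.quantile(1e-300, synth_params) < 1e-10
        # x increases toward gamma as u -> 1
        q1 = op.quantile(1 - 1e-9, synth_params)
        q2 = op.quantile(1 - 1e-15, synth_params)
        assert q1 < q2 < synth_params.gamma_
        # a small-exponent law reaches the endpoint within float resolution
        tight = op.OmegaParams(0.5, 0.8, 5.0)
        assert op.quantile(1 - 1e-15, tight) == pytest.approx(
            tight.gamma_, rel=1e-2
        )

    def test_median_against_bisection_oracle(self, running_params):
        from scipy.optimize import brentq

        med = op.quantile(0.5, running_params)
        oracle = brentq(
            lambda x: op.cdf(x, running_params) - 0.5,
            1e-9, running_params.gamma_ - 1e-9, xtol=1e-13,
        )
        assert med == pytest.approx(oracle, rel=1e-9)

    def test_domain_error(self, synth_params):
        for u in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(DomainError):
                op.quantile(u, synth_params)


class TestRandomVariates:
    def test_support_and_reproducibility(self, synth_params):
        x = op.rvs(synth_params, 1000, seed=7)
        assert np.all((x > 0) & (x < synth_params.gamma_))
        y = op.rvs(synth_params, 1000, seed=7)
        np.testing.assert_array_equal(x, y)

    def test_mean_matches_moments(self, running_params):
        s = op.moments(running_params)
        x = op.rvs(running_params, 100_000, seed=123)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - s.mu) < 3 * se

    def test_ks_against_cdf(self, running_params):
        x = op.rvs(running_params, 10_000, seed=5)
        d = stats.kstest(x, lambda v: op.cdf(v, running_params)).statistic
        assert d < 1.63 / np.sqrt(10_000)  # 99% point of the Kolmogorov law


class TestMoments:
    def test_running_example_values(self, running_params):
        """Frozen from the adaptive-quadrature oracle run before the build."""
        s = op.moments(running_params)
        assert s.mu == pytest.approx(0.5089010, abs=5e-7)
        assert s.sigma == pytest.approx(0.2095283, abs=5e-7)
        assert s.a_exp == pytest.approx(84888.587, rel=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_mu_identity(self, seed):
        """mu = alpha * k * gamma^(beta+1) holds by construction of k."""
        params = random_valid_params(np.random.default_rng(100 + seed))
        s = op.moments(params)
        assert s.mu == pytest.approx(
            params.alpha * s.k * params.gamma_ ** (params.beta + 1.0), rel=1e-8
        )

    def test_closed_form_matches_quadrature_sweep(self):
        """Dual-path contract at 1e-6 relative, including the huge exponent."""
        rng = np.random.default_rng(3)
        cases = [random_valid_params(rng) for _ in range(6)]
        cases.append(op.OmegaParams(4.28, 2.61, 57.79))  # a_exp ~ 8.5e4
        for params in cases:
            mu_c, sig_c = _moments_closed(
                params.alpha, params.beta, params.gamma_
            )
            pts = [float(op.quantile(u, params)) for u in (1e-9, 0.5, 1 - 1e-9)]
            mu_q, _ = integrate.quad(
                lambda x: x * op.pdf(x, params), 0, params.gamma_,
                limit=300, points=pts,
            )
            m2_q, _ = integrate.quad(
                lambda x: x * x * op.pdf(x, params), 0, params.gamma_,
                limit=300, points=pts,
            )
            assert mu_c == pytest.approx(mu_q, rel=1e-6)
            assert sig_c**2 + mu_c**2 == pytest.approx(m2_q, rel=1e-6)

    def test_against_high_precision_oracle(self):
        """Independent arbitrary-precision evaluation of the same closed form."""
        mp = pytest.importorskip("mpmath")
        mp.mp.dps = 40
        for alpha, beta, gamma_ in [(2.0, 1.5, 10.0), (4.28, 2.61, 57.79)]:
            a_, b_, g_ = mp.mpf(alpha), mp.mpf(beta), mp.mpf(gamma_)
            a = a_ * g_**b_ / 2

            def ex(p):
                c = p / b_ + a + 1
                F = mp.hyp2f1(p / b_, p / b_ + 1, c, mp.mpf(1) / 2)
                logpre = (
                    mp.log(a_) + (b_ + p) * mp.log(g_)
                    + mp.loggamma(p / b_ + 1) + mp.loggamma(a)
                    - mp.loggamma(c) - (p / b_ + 1) * mp.log(2)
                )
                return mp.e**logpre * F

            mu_o = float(ex(1))
            sig_o = float(mp.sqrt(ex(2) - ex(1) ** 2))
            s = op.moments(op.OmegaParams(alpha, beta, gamma_))
            assert s.mu == pytest.approx(mu_o, rel=1e-8)
            assert s.sigma == pytest.approx(sig_o, rel=1e-8)

    def test_weibull_limit_of_log_survival(self):
        """For huge a_exp and x << gamma, log S(x) ~ -alpha x^beta."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            params = random_valid_params(
                rng, beta_range=(1.5, 5.0), log_a_range=(np.log(1e3), 13.8)
            )
            x = rng.uniform(0.01, 0.1) * params.gamma_
            target = -params.alpha * x**params.beta
            assert abs(op.log_survival(x, params) - target) <= 1e-3 * abs(target)
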