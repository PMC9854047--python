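"""Conditional-update correctness against closed-form and numeric oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from phospec.models import CARModel, IndependentModel, loglik
from phospec.priors import SpikeSlabPrior
from phospec.sampling import (
    car_logdet,
    car_quadform,
    gaussian_loglik,
    loglik_car,
    sweep_coefficients,
    update_phi_mh,
    update_variance,
    update_w,
)
from phospec.simulate import SimulationConfig, simulate_dataset
from phospec.spatial import build_layout, euclidean_distances, exp_correlation


class TestLoglik:
    def test_standard_normal_at_zero(self):
        ll = loglik("independent", [0.0], [[0.0]], {"beta": [1.0], "sigma2": 1.0})
        assert ll == pytest.approx(math.log(1.0 / math.sqrt(2 * math.pi)))

    def test_car_phi_zero_is_weighted_independent(self, chain3):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(3)
        X = rng.standard_normal((3, 2))
        beta = rng.standard_normal(2)
        tau2 = 0.7
        ll = loglik("car", y, X, {"beta": beta, "tau2": tau2, "phi": 0.0}, fs=chain3)
        # per-plot variances tau2 / m_i. at phi = 0
        resid = y - X @ beta
        expected = sum(
            stats.norm.logpdf(resid[i], scale=math.sqrt(tau2 / chain3.d_m[i]))
            for i in range(3)
        )
        assert ll == pytest.approx(expected)

    def test_car_matches_dense_mvn_oracle(self, chain3):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(3)
        X = rng.standard_normal((3, 2))
        beta = np.array([0.3, -1.1])
        tau2, phi = 0.9, 0.4
        ll = loglik("car", y, X, {"beta": beta, "tau2": tau2, "phi": phi}, fs=chain3)
        # oracle: explicitly invert the precision and use scipy's MVN
        P = (np.diag(chain3.d_m) - phi * chain3.M) / tau2
        expected = stats.multivariate_normal.logpdf(y, X @ beta, np.linalg.inv(P))
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_geostat_conditional_on_field(self):
        y = np.array([1.0, 2.0])
        X = np.eye(2)
        w = np.array([0.5, -0.5])
        ll = loglik(
            "geostat", y, X, {"beta": [0.0, 0.0], "w": w, "tau2": 2.0}
        )
        expected = stats.norm.logpdf(y - w, scale=math.sqrt(2.0)).sum()
        assert ll == pytest.approx(expected)


def _single_sweep_inclusion_freq(x, y, sigma2, prior, n_sweeps=4000, seed=0):
    """Empirical inclusion frequency over repeated conditional draws."""
    rng = np.random.default_rng(seed)
    p0, mu, nu = prior.expand(1)
    G = np.array([[float(x @ x)]])
    include = 0
    beta = np.zeros(1)
    gamma = np.ones(1, dtype=np.int8)
    for _ in range(n_sweeps):
        beta[0] = 0.0
        g = np.array([float(x @ y)])
        sweep_coefficients(
            G, g, beta, gamma, 1.0 / sigma2, p0, mu, nu,
            np.array([True]), np.array([0]), rng.random(1), rng.standard_normal(1),
        )
        include += int(gamma[0])
    return include / n_sweeps


def _marginal_lik_ratio(x, y, sigma2, mu, nu):
    """Numeric-integration oracle for the slab/spike Bayes factor."""

    def integrand(b):
        resid = y - x * b
        return math.exp(
            gaussian_loglik(resid, sigma2) + stats.norm.logpdf(b, mu, math.sqrt(nu))
        )

    m1, _ = integrate.quad(integrand, mu - 12 * math.sqrt(nu), mu + 12 * math.sqrt(nu))
    m0 = math.exp(gaussian_loglik(y, sigma2))
    return m1 / m0


class TestSpikeSlabUpdate:
    def test_degenerate_slab_recovers_prior(self):
        # nu -> 0 with mu = 0: slab indistinguishable from spike, so the
        # posterior inclusion probability equals the prior 1 - p0
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        prior = SpikeSlabPrior(p0=0.3, mu=0.0, nu=1e-12)
        freq = _single_sweep_inclusion_freq(x, y, 1.0, prior, seed=2)
        assert freq == pytest.approx(0.7, abs=0.03)

    def test_strong_signal_always_included(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        y = 2.0 * x + 0.01 * rng.standard_normal(50)
        prior = SpikeSlabPrior(p0=0.5, mu=0.0, nu=1.0)
        freq = _single_sweep_inclusion_freq(x, y, 1.0, prior, n_sweeps=1000, seed=4)
        assert freq > 0.95
        # and the conditional probability matches the integration oracle
        bf = _marginal_lik_ratio(x, y, 1.0, 0.0, 1.0)
        assert bf > 1e6  # overwhelming evidence for inclusion

    @pytest.mark.parametrize("scale", [0.15, 0.6])
    def test_inclusion_frequency_matches_bayes_factor(self, scale):
        # moderate-evidence regime where the probability is interior
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        y = scale * x + rng.standard_normal(30)
        prior = SpikeSlabPrior(p0=0.5, mu=0.0, nu=1.0)
        bf = _marginal_lik_ratio(x, y, 1.0, 0.0, 1.0)
        expected = bf / (1.0 + bf)  # prior odds 1
        freq = _single_sweep_inclusion_freq(x, y, 1.0, prior, n_sweeps=8000, seed=9)
        se = math.sqrt(expected * (1 - expected) / 8000)
        assert freq == pytest.approx(expected, abs=4 * se + 0.005)

    def test_orthonormal_joint_posterior_enumeration(self):
        # p = 2 orthonormal predictors: the gamma posterior factorizes and
        # can be enumerated exactly from per-coordinate Bayes factors
        rng = np.random.default_rng(11)
        A = rng.standard_normal((24, 2))
        Q, _ = np.linalg.qr(A)
        X = Q  # orthonormal columns
        y = 0.8 * X[:, 0] + 0.1 * X[:, 1] + 0.3 * rng.standard_normal(24)
        sigma2 = 0.09
        prior = SpikeSlabPrior(p0=0.5, mu=0.0, nu=1.0)
        bfs = [
            _marginal_lik_ratio(X[:, j], y, sigma2, 0.0, 1.0) for j in range(2)
        ]
        exact_pip = np.array([bf / (1 + bf) for bf in bfs])

        p0, mu, nu = prior.expand(2)
        G = X.T @ X
        beta = np.zeros(2)
        gamma = np.ones(2, dtype=np.int8)
        counts = np.zeros(2)
        n_sweeps = 6000
        grng = np.random.default_rng(12)
        for _ in range(n_sweeps):
            g = X.T @ y - G @ beta
            sweep_coefficients(
                G, g, beta, gamma, 1.0 / sigma2, p0, mu, nu,
                np.array([True, True]), grng.permutation(2),
                grng.random(2), grng.standard_normal(2),
            )
            counts += gamma
        freq = counts / n_sweeps
        assert np.allclose(freq, exact_pip, atol=0.03)


class TestVarianceUpdate:
    def test_zero_residuals_leave_rate_unchanged(self):
        # IG(0.01 + n/2, 0.01): check the draws against the analytic mean
        rng = np.random.default_rng(0)
        n = 50
        draws = [update_variance(rng, 0.01, 0.01, n, 0.0) for _ in range(20000)]
        expected_mean = 0.01 / (0.01 + n / 2 - 1)
        assert np.mean(draws) == pytest.approx(expected_mean, rel=0.05)

    def test_conditional_moments_match_ig(self):
        rng = np.random.default_rng(1)
        n = 100
        resid = np.random.default_rng(2).standard_normal(n)
        quad = float(resid @ resid)
        shape, rate = 0.01 + n / 2, 0.01 + quad / 2
        draws = np.array(
            [update_variance(rng, 0.01, 0.01, n, quad) for _ in range(10000)]
        )
        ig_mean = rate / (shape - 1)
        ig_sd = math.sqrt(rate**2 / ((shape - 1) ** 2 * (shape - 2)))
        mc_se = ig_sd / math.sqrt(10000)
        assert draws.mean() == pytest.approx(ig_mean, abs=3 * mc_se)

    def test_car_quadform_phi_zero_scalar_expansion(self, pair):
        resid = np.array([0.7, -1.3])
        q = car_quadform(resid, pair.d_m, pair.M, 0.0)
        assert q == pytest.approx(float(np.sum(pair.d_m * resid**2)))

    def test_negative_quadform_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            update_variance(rng, 0.01, 0.01, 5, -1.0)


class TestPhiMetropolis:
    def test_zero_proposal_sd_keeps_chain_constant(self):
        rng = np.random.default_rng(0)
        phi = 0.3
        for _ in range(50):
            phi, acc, _ = update_phi_mh(phi, lambda p: 0.0, 0.0, 1.0, 0.0, rng)
            assert not acc
        assert phi == 0.3

    def test_flat_target_samples_uniform(self):
        # likelihood free of phi: the stationary law is the uniform prior
        rng = np.random.default_rng(42)
        phi = 0.5
        draws = []
        for it in range(50000):
            phi, _, _ = update_phi_mh(phi, lambda p: 0.0, 0.0, 1.0, 2.5, rng)
            if it % 5 == 4:
                draws.append(phi)
        stat = stats.kstest(draws, "uniform")
        assert stat.pvalue > 0.01

    def test_posterior_matches_grid_oracle(self, chain3):
        # 3-plot chain with data favouring positive dependence: compare the
        # MH chain with the exact posterior evaluated on a fine phi grid
        fs = chain3
        tau2 = 0.25
        y = np.array([1.0, 1.1, 0.9])  # strongly positively correlated
        lo, hi = fs.phi_support

        def logpost(phi):
            ld = car_logdet(fs.d_m, fs.eigenvalues, phi)
            return loglik_car(y, tau2, fs.d_m, fs.M, phi, ld)

        grid = np.linspace(lo + 1e-4, hi - 1e-4, 4001)
        lp = np.array([logpost(p) for p in grid])
        wgt = np.exp(lp - lp.max())
        wgt /= wgt.sum()
        grid_mean = float(grid @ wgt)
        grid_p_pos = float(wgt[grid > 0].sum())

        rng = np.random.default_rng(7)
        phi, cur = 0.0, None
        draws = []
        for it in range(40000):
            phi, _, cur = update_phi_mh(
                phi, logpost, lo, hi, 1.5, rng, current_log_target=cur
            )
            if it >= 2000:
                draws.append(phi)
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(grid_mean, abs=0.03)
        assert np.mean(draws > 0) == pytest.approx(grid_p_pos, abs=0.05)
        assert grid_p_pos > 0.9  # the signal really is informative


class _MeanOnlyRng:
    """Stub generator whose normals are zero: update_w returns its mean."""

    def standard_normal(self, n):
        return np.zeros(n)


class TestLatentFieldUpdate:
    def _setup(self, sigma2, tau2):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        H = exp_correlation(euclidean_distances(coords), 0.5)
        resid = np.array([1.2, -0.4])
        return resid, H, sigma2, tau2

    def test_prior_dominates_when_sigma2_vanishes(self):
        resid, H, *_ = self._setup(1e-10, 1.0)
        rng = np.random.default_rng(0)
        w = update_w(resid, H, 1e-10, 1.0, rng)
        assert np.linalg.norm(w) < 1e-4

    def test_two_site_closed_form_mean_and_cov(self):
        resid, H, sigma2, tau2 = self._setup(0.8, 0.5)
        # closed-form bivariate conditioning oracle
        A = np.linalg.inv(H) / sigma2 + np.eye(2) / tau2
        cov = np.linalg.inv(A)
        mean = cov @ (resid / tau2)
        w_mean = update_w(resid, H, sigma2, tau2, _MeanOnlyRng())
        assert np.allclose(w_mean, mean, atol=1e-8)
        rng = np.random.default_rng(1)
        draws = np.array([update_w(resid, H, sigma2, tau2, rng) for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), mean, atol=0.05)
        assert np.allclose(np.cov(draws.T), cov, atol=0.05)

    def test_data_dominate_when_tau2_vanishes(self):
        resid, H, *_ = self._setup(1.0, 1e-10)
        w = update_w(resid, H, 1.0, 1e-10, _MeanOnlyRng())
        assert np.allclose(w, resid, atol=1e-4)

    def test_ill_conditioned_h_reports_condition_number(self):
        H = np.ones((3, 3)) + 1e-14 * np.eye(3)
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            update_w(np.zeros(3), H, 1.0, 1.0, np.random.default_rng(0))


class TestFitContracts:
    def test_same_seed_bit_identical_chains(self):
        cfg = SimulationConfig(seed=0, n=40)
        X, beta, y = simulate_dataset(cfg)
        kwargs = dict(n_iter=400, burn_in=200, thin=2, seed=9)
        r1 = IndependentModel(y, X[:, :20]).fit(**kwargs)
        r2 = IndependentModel(y, X[:, :20]).fit(**kwargs)
        assert np.array_equal(r1.samples.beta, r2.samples.beta)
        assert np.array_equal(r1.samples.sigma2, r2.samples.sigma2)
        assert np.array_equal(r1.deviance, r2.deviance)

    def test_sparsity_beta_zero_iff_gamma_zero(self):
        cfg = SimulationConfig(seed=1, n=60)
        X, beta, y = simulate_dataset(cfg)
        res = IndependentModel(y, X[:, :30]).fit(n_iter=600, burn_in=200, thin=2, seed=3)
        s = res.samples
        assert np.array_equal(s.beta != 0.0, s.gamma == 1)

    def test_draw_count_matches_config(self):
        cfg = SimulationConfig(seed=2, n=30)
        X, _, y = simulate_dataset(cfg)
        res = IndependentModel(y, X[:, :10]).fit(n_iter=500, burn_in=100, thin=4, seed=0)
        assert res.n_draws == 100
        assert res.samples.sigma2.size == 100

    def test_car_fit_phi_stays_in_support(self, chain3):
        fs = build_layout(4, 4)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(16)
        X = rng.standard_normal((16, 3))
        res = CARModel(y, X, field=fs).fit(n_iter=600, burn_in=200, thin=2, seed=5)
        lo, hi = fs.phi_support
        assert np.all((res.samples.phi > lo) & (res.samples.phi < hi))
        assert np.all(res.samples.tau2 > 0)


class TestGettingItRight:
    def test_successive_conditional_matches_prior_moments(self):
        # Geweke-style check on a 6-plot, 4-predictor independent model:
        # alternately drawing theta | y (our kernels) and y | theta (the
        # sampling model) must leave the prior marginals invariant
        n, p = 6, 4
        rng = np.random.default_rng(123)
        X = rng.standard_normal((n, p))
        G = X.T @ X
        alpha, eta = 3.0, 2.0
        p0 = np.full(p, 0.5)
        mu = np.zeros(p)
        nu = np.full(p, 0.5)
        selectable = np.ones(p, dtype=bool)
        beta = np.zeros(p)
        gamma = np.ones(p, dtype=np.int8)
        sigma2 = 1.0
        n_iter, keep_from = 30000, 500
        kept_beta0, kept_gamma, kept_sigma2 = [], [], []
        for it in range(n_iter):
            y = X @ beta + math.sqrt(sigma2) * rng.standard_normal(n)
            g = X.T @ y - G @ beta
            sweep_coefficients(
                G, g, beta, gamma, 1.0 / sigma2, p0, mu, nu,
                selectable, rng.permutation(p), rng.random(p),
                rng.standard_normal(p),
            )
            resid = y - X @ beta
            sigma2 = update_variance(rng, alpha, eta, n, float(resid @ resid))
            if it >= keep_from:
                kept_beta0.append(beta[0])
                kept_gamma.append(gamma.mean())
                kept_sigma2.append(sigma2)
        kept_beta0 = np.array(kept_beta0)
        # prior marginals: gamma_j ~ Bern(0.5); beta_j ~ 0.5 delta0 + 0.5 N(0, 0.5)
        # => E beta = 0, Var beta = 0.25; sigma2 ~ IG(3, 2) => mean 1, sd 1
        assert np.mean(kept_gamma) == pytest.approx(0.5, abs=0.02)
        assert kept_beta0.mean() == pytest.approx(0.0, abs=0.03)
        assert kept_beta0.var() == pytest.approx(0.25, abs=0.04)
        assert np.mean(kept_sigma2) == pytest.approx(1.0, abs=0.08)

    def test_car_loglik_weighted_independent_identity_random_data(self):
        # exact identity at phi = 0, any data
        fs = build_layout(3, 4)
        rng = np.random.default_rng(9)
        for _ in range(5):
            resid = rng.standard_normal(12)
            tau2 = float(rng.uniform(0.2, 2.0))
            ld = car_logdet(fs.d_m, fs.eigenvalues, 0.0)
            ll = loglik_car(resid, tau2, fs.d_m, fs.M, 0.0, ld)
            expected = sum(
                stats.norm.logpdf(resid[i], scale=math.sqrt(tau2 / fs.d_m[i]))
                for i in range(12)
            )
            assert ll == pytest.approx(expected)
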