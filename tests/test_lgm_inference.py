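"""Latent Gaussian model: precision assembly, Laplace approximation,
hyperparameter integration and posterior profiles, all against dense
brute-force oracles on small instances."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logsumexp
from scipy.stats import gamma

from bayesdmr.config import InferenceConfig
from bayesdmr.io_preprocess import chunk_genome
from bayesdmr.lgm_inference import (Hyperparameters, build_joint_precision,
                                    explore_hyperparameters,
                                    gaussian_approximation,
                                    log_marginal_theta,
                                    overdispersion_variance,
                                    posterior_profiles, run_inference)
from bayesdmr.lgm_inference import (_gauss_hermite_expit, _log_prior_theta,
                                    _takahashi_band)

from conftest import (band_to_dense, dense_newton_oracle, make_chunk,
                      make_table, rw1_dense_precision, simulate_generative)

EPS = 1e-5
NAN2 = lambda m: np.full((m, 2), np.nan)


class TestPrecisionAssembly:
    def test_single_site_no_data_is_anchor_only(self):
        ch = make_chunk([50], NAN2(1), NAN2(1), [0, 1])
        ps = build_joint_precision(ch, 0, Hyperparameters(rho2=0.01), EPS)
        assert ps.n == 1
        assert ps.ab[0, 0] == pytest.approx(EPS)

    def test_rw1_tridiagonal_values(self):
        # rho2 = 0.01/bp, 100 bp gaps -> increment precision exactly 1
        ch = make_chunk([100, 200, 300], NAN2(3), NAN2(3), [0, 1])
        ps = build_joint_precision(ch, 0, Hyperparameters(rho2=0.01), EPS)
        assert np.allclose(ps.ab[0], [1 + EPS, 2 + EPS, 1 + EPS])
        assert np.allclose(ps.ab[1], [-1, -1, 0])

    def test_matches_inverse_of_generative_covariance(self):
        # 4 CpGs x 2 replicates: brute-force covariance of (eta, mu) from
        # the generative equations, inverted, equals the assembled precision
        pos = [10, 150, 400, 450]
        total = np.array([[10, 12, 8, 9], [5, 7, 11, 6],
                          [9, 9, 9, 9], [10, 10, 10, 10]], dtype=float)
        meth = np.floor(total * 0.6)
        ch = make_chunk(pos, meth, total, [0, 0, 1, 1])
        th = Hyperparameters(rho2=0.005, sigma2=0.3)
        ps = build_joint_precision(ch, 0, th, EPS)
        S_mu = np.linalg.inv(rw1_dense_precision(pos, th.rho2, EPS))
        n = 12  # per site: eta_r1, eta_r2, mu
        C = np.zeros((n, n))
        mu_of = lambda i: 3 * i + 2
        for i in range(4):
            for j in range(4):
                C[mu_of(i), mu_of(j)] = S_mu[i, j]
                for a in range(2):
                    C[3 * i + a, mu_of(j)] = S_mu[i, j]
                    C[mu_of(j), 3 * i + a] = S_mu[i, j]
                    for b in range(2):
                        C[3 * i + a, 3 * j + b] = S_mu[i, j] + (
                            th.sigma2 if (i == j and a == b) else 0.0)
        assert np.allclose(band_to_dense(ps.ab), np.linalg.inv(C),
                           atol=1e-8)
        assert np.array_equal(ps.mu_index, [2, 5, 8, 11])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(Exception):
            ch = make_chunk([100, 100], NAN2(2), NAN2(2), [0, 1])
            build_joint_precision(ch, 0, Hyperparameters(rho2=0.01))

    def test_takahashi_matches_dense_inverse(self, rng):
        from scipy.linalg import cholesky_banded
        pos = np.cumsum(rng.integers(10, 300, 6))
        total = rng.poisson(10.0, (6, 4)).astype(float)
        meth = np.floor(total / 2)
        ch = make_chunk(pos, meth, total, [0, 0, 1, 1])
        ps = build_joint_precision(ch, 0,
                                   Hyperparameters(rho2=0.01, sigma2=0.2))
        cb = cholesky_banded(ps.ab, lower=True)
        S = _takahashi_band(cb)
        dense = np.linalg.inv(band_to_dense(ps.ab))
        for k in range(ps.ab.shape[0]):
            for j in range(ps.n - k):
                assert S[k, j] == pytest.approx(dense[j + k, j],
                                                rel=1e-9, abs=1e-9)


class TestGaussianApproximation:
    def test_symmetric_counts_give_zero_mode(self):
        m = 8
        total = np.full((m, 4), 200.0)
        meth = total / 2
        ch = make_chunk(np.arange(1, m + 1) * 100, meth, total, [0, 0, 1, 1])
        ga = gaussian_approximation(ch, 0,
                                    Hyperparameters(rho2=0.01, sigma2=0.1))
        assert np.max(np.abs(ga.mu_mean)) < 1e-3

    def test_single_site_matches_numeric_oracle(self):
        # weak prior: posterior mode ~ MLE logit(0.9)
        ch = make_chunk([100], [[9.0, 0.0]], [[10.0, 1.0]], [0, 1])
        ga = gaussian_approximation(ch, 0, Hyperparameters(rho2=1000.0))
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(
            lambda u: -(9 * u - 10 * np.logaddexp(0, u) - 0.5 * EPS * u * u),
            bounds=(-8, 8), method="bounded")
        assert ga.mu_mean[0] == pytest.approx(res.x, abs=1e-4)
        assert abs(ga.mu_mean[0] - np.log(9.0)) < 0.05

    def test_matches_dense_newton_oracle(self, rng):
        pos = np.cumsum(rng.integers(20, 400, 5))
        total = rng.poisson(15.0, (5, 4)).astype(float)
        meth = rng.binomial(total.astype(int), 0.7).astype(float)
        ch = make_chunk(pos, meth, total, [0, 0, 1, 1])
        th = Hyperparameters(rho2=0.02, sigma2=0.15)
        ps = build_joint_precision(ch, 0, th, EPS)
        ga = gaussian_approximation(ch, 0, th)
        x, cov = dense_newton_oracle(band_to_dense(ps.ab), ps.lik_index,
                                     ps.lik_y, ps.lik_n)
        assert np.allclose(ga.mode, x, atol=1e-8)
        assert np.allclose(ga.mu_var, np.diag(cov)[ps.mu_index], atol=1e-8)

    def test_zero_coverage_site_is_interpolated(self):
        total = np.array([[10, 10], [np.nan, np.nan], [10, 10]])
        meth = np.array([[9, 9], [np.nan, np.nan], [1, 1]])
        ch = make_chunk([100, 200, 300], meth, total, [0, 1])
        ga = gaussian_approximation(ch, 0,
                                    Hyperparameters(rho2=0.01, sigma2=0.1))
        assert ga.mu_mean[0] > ga.mu_mean[1] > ga.mu_mean[2]


class TestLogMarginal:
    def test_gamma_prior_has_mean_one_variance_ten(self):
        prior = gamma(a=0.1, scale=1.0 / 0.1)
        assert prior.mean() == pytest.approx(1.0)
        assert prior.var() == pytest.approx(10.0)

    def test_no_data_posterior_equals_prior(self):
        ch = make_chunk([100, 300, 800], NAN2(3), NAN2(3), [0, 1])
        vals = []
        for rho2 in (0.1, 1.0, 10.0):
            th = Hyperparameters(rho2=rho2)
            vals.append(log_marginal_theta(ch, 0, th) - _log_prior_theta(th))
        assert max(vals) - min(vals) < 1e-6

    @pytest.mark.parametrize("rho2", [0.002, 0.01])
    def test_matches_dense_quadrature_oracle(self, rho2):
        pos = [100, 250, 320]
        meth = np.array([[3, 1], [7, 2], [6, 1]], dtype=float)
        total = np.array([[10, 9], [10, 8], [9, 7]], dtype=float)
        ch = make_chunk(pos, meth, total, [0, 1])
        th = Hyperparameters(rho2=rho2)
        lm = log_marginal_theta(ch, 0, th)
        # brute force: midpoint cubature of the 3-D latent integral
        Q = rw1_dense_precision(pos, rho2, EPS)
        ga = gaussian_approximation(ch, 0, th)
        sd = np.sqrt(ga.mu_var)
        axes = [np.linspace(ga.mu_mean[i] - 7 * sd[i],
                            ga.mu_mean[i] + 7 * sd[i], 121)
                for i in range(3)]
        G = np.meshgrid(*axes, indexing="ij")
        X = np.stack([g.ravel() for g in G], axis=1)
        y, n = meth[:, 0], total[:, 0]
        ll = X @ y - np.logaddexp(0, X) @ n
        quad = -0.5 * np.einsum("ij,jk,ik->i", X, Q, X)
        _, logdet = np.linalg.slogdet(Q)
        log_px = 0.5 * logdet - 1.5 * np.log(2 * np.pi) + quad
        dv = np.prod([a[1] - a[0] for a in axes])
        oracle = logsumexp(ll + log_px) + np.log(dv) + _log_prior_theta(th)
        assert lm == pytest.approx(oracle, abs=0.1)


@pytest.fixture(scope="module")
def grid():
    chunk, _ = simulate_generative(120, 2, 20, 0.1, 0.02, seed=5)
    return explore_hyperparameters(chunk, 0)


class TestHyperparameterExploration:
    def test_weights_normalized_nonnegative(self, grid):
        assert np.all(grid.weights >= 0)
        assert np.sum(grid.weights) == pytest.approx(1.0)

    def test_mode_point_has_maximal_weight(self, grid):
        assert np.argmax(grid.weights) == grid.mode_index

    def test_single_replicate_collapses(self):
        chunk, _ = simulate_generative(60, 1, 20, 0.0, 0.02, seed=6)
        grid = explore_hyperparameters(chunk, 0)
        assert grid.collapsed
        assert all(p.sigma2 is None for p in grid.points)


class TestPosteriorProfiles:
    def test_quadrature_matches_monte_carlo(self):
        e1, _ = _gauss_hermite_expit(np.array([1.0]), np.array([1.0]))
        z = np.random.default_rng(1).normal(1.0, 1.0, 10**6)
        mc, se = expit(z).mean(), expit(z).std() / 1000.0
        assert abs(e1[0] - mc) < 3 * se

    def test_degenerate_marginal_at_zero_gives_half(self):
        e1, _ = _gauss_hermite_expit(np.array([0.0]), np.array([1e-14]))
        assert e1[0] == pytest.approx(0.5)

    def test_group_swap_negates_d_exactly(self, rng):
        total = rng.poisson(20.0, (15, 4)).astype(float)
        probs = np.where(np.arange(15)[:, None] < 8, 0.8, 0.3)
        meth = rng.binomial(total.astype(int),
                            np.repeat(probs, 4, 1) * 0 + probs).astype(float)
        pos = np.cumsum(rng.integers(20, 200, 15))
        ch1 = make_chunk(pos, meth, total, [0, 0, 1, 1])
        ch2 = make_chunk(pos, meth, total, [1, 1, 0, 0])
        p1 = posterior_profiles(ch1)
        p2 = posterior_profiles(ch2)
        assert np.array_equal(p1["d"].to_numpy(), -p2["d"].to_numpy())

    def test_posterior_means_inside_unit_interval(self):
        chunk, _ = simulate_generative(50, 2, 15, 0.1, 0.02, seed=9)
        prof = posterior_profiles(chunk)
        for col in ("meanmeth_g1", "meanmeth_g2"):
            assert np.all((prof[col] > 0) & (prof[col] < 1))
        assert np.all(np.abs(prof["d"]) <= 1)


class TestShrinkageAndPriorCorrelation:
    def test_prior_correlation_nonincreasing_with_distance(self, rng):
        # sample the anchored RW(1) prior and check corr(mu_0, mu_j) decays
        pos = [100, 200, 300, 400, 500]
        Q = rw1_dense_precision(pos, 0.01, 1e-3)
        C = np.linalg.inv(Q)
        L = np.linalg.cholesky(C)
        draws = (L @ rng.normal(size=(5, 40000))).T
        corr = np.corrcoef(draws, rowvar=False)[0]
        assert np.all(np.diff(corr) < 0)

    def test_smoothing_limits(self, rng):
        m = 12
        total = np.full((m, 2), 40.0)
        meth = np.tile([[36.0, 4.0]], (m // 2, 1)).reshape(-1, 1)
        meth = np.column_stack([meth, meth])
        pos = np.arange(1, m + 1) * 100
        ch = make_chunk(pos, meth, total, [0, 1])
        # rho2 -> 0: profile approaches a constant
        ga_smooth = gaussian_approximation(
            ch, 0, Hyperparameters(rho2=1e-9))
        assert np.ptp(ga_smooth.mu_mean) < 1e-3
        # rho2 -> inf: profile approaches per-site empirical logits
        ga_rough = gaussian_approximation(
            ch, 0, Hyperparameters(rho2=1e4))
        emp = np.log(meth[:, 0] / (total[:, 0] - meth[:, 0]))
        assert np.allclose(ga_rough.mu_mean, emp, atol=1e-2)


class TestOverdispersion:
    def test_no_latent_variance_is_pure_binomial(self):
        assert overdispersion_variance(10, 0.0, 0.0, 0.0) == pytest.approx(2.5)

    def test_single_read_has_no_overdispersion(self):
        assert overdispersion_variance(1, 0.7, 0.5, 0.9) == pytest.approx(
            expit(0.7) * (1 - expit(0.7)))

    def test_matches_monte_carlo_generative_variance(self, rng):
        n, mu, var_latent = 10, 0.0, 0.4
        eta = mu + rng.normal(0, np.sqrt(var_latent), 10**6)
        ydraw = rng.binomial(n, expit(eta))
        formula = overdispersion_variance(n, mu, 0.25, 0.15)
        assert formula == pytest.approx(np.var(ydraw), rel=0.10)


class TestRunInference:
    def _two_chunk_table(self, rng):
        pos = np.concatenate([np.arange(1, 11) * 50,
                              5000 + np.arange(1, 11) * 50])
        total = rng.poisson(15.0, (20, 4)).astype(float)
        meth = rng.binomial(total.astype(int), 0.5).astype(float)
        return make_table(pos, meth, total, [0, 0, 1, 1])

    def test_genome_run_equals_per_chunk_concatenation(self, rng):
        table = self._two_chunk_table(rng)
        cfg = InferenceConfig()
        full = run_inference(table, cfg)
        parts = pd.concat([posterior_profiles(c, cfg)
                           for c in chunk_genome(table, cfg.gap_threshold)],
                          ignore_index=True)
        assert np.array_equal(full["d"].to_numpy(), parts["d"].to_numpy())
        assert np.array_equal(full["meanmeth_g1"].to_numpy(),
                              parts["meanmeth_g1"].to_numpy())

    def test_empty_table_gives_empty_profile(self):
        from bayesdmr.io_preprocess import read_counts
        empty = read_counts([], {}, dialect="generic")
        prof = run_inference(empty)
        assert len(prof) == 0
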