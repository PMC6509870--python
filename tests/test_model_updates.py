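"""Each closed-form CAVI update against an independent loop-based oracle,
plus the direct-substitution special cases of the update equations."""

import numpy as np
import pytest

from vpac.model import (
    Hyperparameters,
    expected_moments,
    update_ard,
    update_component_means,
    update_component_precisions,
    update_latent,
    update_mixture_weights,
    update_noise,
    update_offset,
    update_projection,
    update_responsibilities,
)

import _oracles as oracle
from conftest import random_state


def _random_instance(rng, N, D, L, M):
    hyper = Hyperparameters(M=M, L=L)
    st = random_state(rng, N, D, L, M, hyper)
    X = rng.standard_normal((N, D)) * 2.0
    return st, X, hyper


@pytest.mark.parametrize("trial", range(20))
def test_updates_match_loop_oracles(trial):
    """All nine updates reproduce the loop-coded closed forms on random
    micro-instances (N<=8, D<=6, L<=3, M<=3) to 1e-10 relative error."""
    rng = np.random.default_rng(1000 + trial)
    N = int(rng.integers(3, 9))
    D = int(rng.integers(3, 7))
    L = int(rng.integers(1, min(4, D)))
    M = int(rng.integers(1, 4))
    st, X, hyper = _random_instance(rng, N, D, L, M)
    tol = dict(rtol=1e-10, atol=1e-12)

    mz, cz = oracle.latent_update_loops(st, X)
    out = update_latent(st.copy(), X, hyper)
    np.testing.assert_allclose(out.z_mean, mz, **tol)
    np.testing.assert_allclose(out.z_cov, cz, **tol)

    mw, cw = oracle.projection_update_loops(st, X)
    out = update_projection(st.copy(), X, hyper)
    np.testing.assert_allclose(out.w_mean, mw, **tol)
    np.testing.assert_allclose(out.w_cov, cw, **tol)

    mmu, smu = oracle.offset_update_loops(st, X, hyper.beta)
    out = update_offset(st.copy(), X, hyper)
    np.testing.assert_allclose(out.mu_mean, mmu, **tol)
    np.testing.assert_allclose(out.mu_cov_scalar, smu, **tol)

    sh, ra = oracle.ard_update_loops(st, hyper.a_alpha, hyper.b_alpha)
    out = update_ard(st.copy(), hyper)
    np.testing.assert_allclose(out.alpha_shape, sh, **tol)
    np.testing.assert_allclose(out.alpha_rate, ra, **tol)

    sh, ra = oracle.noise_update_loops(st, X, hyper.a_tau, hyper.b_tau)
    out = update_noise(st.copy(), X, hyper)
    np.testing.assert_allclose(out.tau_shape, sh, **tol)
    np.testing.assert_allclose(out.tau_rate, ra, **tol)

    resp = oracle.responsibilities_update_loops(st)
    out = update_responsibilities(st.copy())
    np.testing.assert_allclose(out.resp, resp, **tol)

    conc = oracle.mixture_weights_update_loops(st, hyper.delta)
    out = update_mixture_weights(st.copy(), hyper)
    np.testing.assert_allclose(out.rho_conc, conc, **tol)

    mm, cm = oracle.component_means_update_loops(st, hyper.gamma)
    out = update_component_means(st.copy(), hyper)
    np.testing.assert_allclose(out.m_mean, mm, **tol)
    np.testing.assert_allclose(out.m_cov, cm, **tol)

    dof, rate = oracle.component_precisions_update_loops(st, hyper.upsilon, hyper.V)
    out = update_component_precisions(st.copy(), hyper)
    np.testing.assert_allclose(out.T_dof, dof, **tol)
    np.testing.assert_allclose(out.T_rate, rate, **tol)


class TestLatentUpdate:
    def test_identity_moments_give_half_identity_covariance(self, rng):
        """With M=1, <T>=I, <tau>=1 and <W'W>=I (L=2), the posterior latent
        covariance is (I + I)^-1 = I/2 for every cell."""
        N, D, L = 4, 3, 2
        st = random_state(rng, N, D, L, 1)
        # force the consumed moments: <tau>=1, <W'W>=I, <T>=I, <m>=0
        st.tau_shape, st.tau_rate = 2.0, 2.0
        st.w_mean = np.zeros((D, L))
        st.w_cov = np.eye(L) / D
        st.T_dof = np.array([float(L)])
        st.T_rate = float(L) * np.eye(L)[None]
        st.m_mean = np.zeros((1, L))
        X = rng.standard_normal((N, D))
        out = update_latent(st, X, Hyperparameters(M=1, L=L))
        np.testing.assert_allclose(out.z_cov, np.broadcast_to(np.eye(L) / 2, (N, L, L)))

    def test_centered_data_and_zero_means_give_zero_latent_mean(self, rng):
        """When x_n = <mu> and all component means vanish, both additive
        terms of the latent-mean update vanish."""
        N, D, L, M = 5, 4, 2, 2
        st = random_state(rng, N, D, L, M)
        st.m_mean = np.zeros((M, L))
        X = np.tile(st.mu_mean, (N, 1))
        out = update_latent(st, X, Hyperparameters(M=M, L=L))
        np.testing.assert_allclose(out.z_mean, 0.0, atol=1e-12)


class TestProjectionUpdate:
    def test_centered_data_gives_zero_projection(self, rng):
        st, X, hyper = _random_instance(rng, 5, 4, 2, 2)
        X = np.tile(st.mu_mean, (5, 1))
        out = update_projection(st, X, hyper)
        np.testing.assert_allclose(out.w_mean, 0.0, atol=1e-12)

    def test_ard_shrinkage_kills_a_column(self, rng):
        """Driving <alpha_i> to a huge value switches off column i of W."""
        st, X, hyper = _random_instance(rng, 6, 5, 3, 2)
        st.alpha_shape = 1.0
        st.alpha_rate = np.array([1.0, 1.0, 1e-14])   # <alpha_2> = 1e14
        out = update_projection(st, X, hyper)
        assert np.max(np.abs(out.w_mean[:, 2])) < 1e-9
        assert np.max(np.abs(out.w_mean[:, :2])) > 1e-3


class TestOffsetUpdate:
    def test_printed_covariance_scalar(self, rng):
        st, X, hyper = _random_instance(rng, 5, 4, 2, 2)
        st.tau_shape, st.tau_rate = 3.0, 3.0      # <tau> = 1
        hyper = Hyperparameters(M=2, L=2, beta=1e-3)
        out = update_offset(st, X, hyper)
        assert out.mu_cov_scalar == pytest.approx(1.0 / (1e-3 + 5.0))

    def test_perfect_reconstruction_gives_zero_offset(self, rng):
        st, _, hyper = _random_instance(rng, 5, 4, 2, 2)
        X = st.z_mean @ st.w_mean.T
        out = update_offset(st, X, hyper)
        np.testing.assert_allclose(out.mu_mean, 0.0, atol=1e-12)


class TestArdUpdate:
    def test_shape_is_prior_plus_half_genes(self, rng):
        st, _, _ = _random_instance(rng, 4, 5, 2, 2)
        st2 = random_state(np.random.default_rng(0), 4, 10, 2, 2)
        hyper = Hyperparameters(M=2, L=2)
        out = update_ard(st2, hyper)
        assert out.alpha_shape == pytest.approx(1e-3 + 5.0)

    def test_zero_column_rate_from_shared_covariance(self, rng):
        """A zero-mean column with w_cov = c*I has <||W_i||^2> = D*c."""
        D, L, c = 6, 2, 0.3
        st = random_state(rng, 4, D, L, 2)
        st.w_mean = np.zeros((D, L))
        st.w_cov = c * np.eye(L)
        out = update_ard(st, Hyperparameters(M=2, L=L))
        np.testing.assert_allclose(out.alpha_rate, 1e-3 + D * c / 2)


class TestNoiseUpdate:
    def test_shape_is_prior_plus_half_nd(self, rng):
        st, X, hyper = _random_instance(rng, 6, 5, 2, 2)
        out = update_noise(st, X, hyper)
        assert out.tau_shape == pytest.approx(1e-3 + 15.0)

    def test_rate_reverts_to_prior_in_noiseless_limit(self, rng):
        """With all posterior covariances collapsed and X = <W><z> + <mu>,
        the expected residual vanishes and the rate reverts to b_tau."""
        st, _, hyper = _random_instance(rng, 5, 4, 2, 2)
        st.z_cov = np.zeros_like(st.z_cov)
        st.w_cov = np.zeros_like(st.w_cov)
        st.m_cov = np.zeros_like(st.m_cov)
        st.mu_cov_scalar = 0.0
        X = st.z_mean @ st.w_mean.T + st.mu_mean
        out = update_noise(st, X, hyper)
        assert out.tau_rate == pytest.approx(hyper.b_tau, rel=1e-6)

    def test_rate_matches_monte_carlo_expectation(self):
        """b_tau-hat equals b_tau + E||x - Wz - mu||^2 / 2 summed over
        cells, with the expectation taken by sampling (W, z, mu) from the
        current factors."""
        rng = np.random.default_rng(7)
        N, D, L, M = 4, 4, 2, 2
        st = random_state(rng, N, D, L, M)
        X = rng.standard_normal((N, D))
        hyper = Hyperparameters(M=M, L=L)
        out = update_noise(st.copy(), X, hyper)

        S = 100_000
        w_chol = np.linalg.cholesky(st.w_cov)
        W = st.w_mean[None] + rng.standard_normal((S, D, L)) @ w_chol.T
        mu = st.mu_mean[None] + np.sqrt(st.mu_cov_scalar) * rng.standard_normal((S, D))
        total = np.zeros(S)
        for n in range(N):
            z_chol = np.linalg.cholesky(st.z_cov[n])
            z = st.z_mean[n][None] + rng.standard_normal((S, L)) @ z_chol.T
            resid = X[n][None] - np.einsum("sdl,sl->sd", W, z) - mu
            total += np.sum(resid**2, axis=1)
        draws = hyper.b_tau + 0.5 * total
        mc_se = draws.std(ddof=1) / np.sqrt(S)
        assert abs(out.tau_rate - draws.mean()) < 3 * mc_se


class TestResponsibilities:
    def test_identical_components_split_evenly(self, rng):
        st = random_state(rng, 5, 4, 2, 2)
        for field in ("m_mean", "m_cov", "T_dof", "T_rate"):
            arr = getattr(st, field)
            arr[1] = arr[0]
        st.rho_conc = np.array([2.0, 2.0])
        out = update_responsibilities(st)
        np.testing.assert_allclose(out.resp, 0.5, atol=1e-12)

    def test_rows_normalise_exactly(self, micro_instance):
        st, X, hyper = micro_instance
        out = update_responsibilities(st)
        np.testing.assert_allclose(out.resp.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(out.resp >= 0) and np.all(out.resp <= 1)


class TestMixtureWeights:
    def test_direct_substitution(self):
        rng = np.random.default_rng(3)
        st = random_state(rng, 100, 4, 2, 2)
        st.resp = np.zeros((100, 2))
        st.resp[:30, 0] = 1.0
        st.resp[30:, 1] = 1.0
        hyper = Hyperparameters(M=2, L=2, delta=np.array([0.5, 0.5]))
        out = update_mixture_weights(st, hyper)
        np.testing.assert_allclose(out.rho_conc, [30.5, 70.5])

    def test_mass_conservation(self, micro_instance):
        st, X, hyper = micro_instance
        out = update_mixture_weights(st, hyper)
        assert out.rho_conc.sum() == pytest.approx(hyper.delta.sum() + st.n_cells)


class TestComponentMeans:
    def test_prior_dominated_limit(self, rng):
        st, _, _ = _random_instance(rng, 6, 5, 2, 2)
        hyper = Hyperparameters(M=2, L=2, gamma=1e12)
        out = update_component_means(st, hyper)
        np.testing.assert_allclose(out.m_mean, 0.0, atol=1e-6)

    def test_sufficient_statistics_limit(self, rng):
        """One component owning every cell with <T>=I and negligible gamma
        recovers the average latent mean."""
        N, L = 8, 2
        st = random_state(rng, N, 4, L, 1)
        st.resp = np.ones((N, 1))
        st.T_dof = np.array([float(L)])
        st.T_rate = float(L) * np.eye(L)[None]
        out = update_component_means(st, Hyperparameters(M=1, L=L, gamma=1e-9))
        np.testing.assert_allclose(out.m_mean[0], st.z_mean.mean(axis=0), rtol=1e-6)


class TestComponentPrecisions:
    def test_dof_direct_substitution(self, rng):
        st = random_state(rng, 10, 4, 2, 2)
        st.resp = np.column_stack([np.ones(10), np.zeros(10)])
        out = update_component_precisions(st, Hyperparameters(M=2, L=2, upsilon=2.0))
        assert out.T_dof[0] == pytest.approx(12.0)

    def test_empty_component_reverts_to_prior(self, rng):
        st = random_state(rng, 6, 4, 2, 2)
        st.resp = np.column_stack([np.ones(6), np.zeros(6)])
        hyper = Hyperparameters(M=2, L=2)
        out = update_component_precisions(st.copy(), hyper)
        assert out.T_dof[1] == pytest.approx(hyper.upsilon)
        np.testing.assert_allclose(out.T_rate[1], hyper.V, atol=1e-12)
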