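import numpy as np
import pytest

from vpac.model import Hyperparameters, VariationalState


def random_spd(rng, size):
    A = rng.standard_normal((size, size))
    return A @ A.T + size * np.eye(size)


def random_state(rng, N, D, L, M, hyper: Hyperparameters | None = None):
    """A random but internally valid variational state for oracle tests."""
    resp = rng.random((N, M)) + 0.05
    resp /= resp.sum(axis=1, keepdims=True)
    return VariationalState(
        z_mean=rng.standard_normal((N, L)),
        z_cov=np.array([random_spd(rng, L) / L for _ in range(N)]),
        w_mean=rng.standard_normal((D, L)),
        w_cov=random_spd(rng, L) / (L * D),
        mu_mean=rng.standard_normal(D),
        mu_cov_scalar=float(rng.random() + 0.1),
        alpha_shape=float(rng.random() * 3 + 0.5),
        alpha_rate=rng.random(L) + 0.5,
        tau_shape=float(rng.random() * 3 + 0.5),
        tau_rate=float(rng.random() + 0.5),
        rho_conc=rng.random(M) + 0.5,
        resp=resp,
        m_mean=rng.standard_normal((M, L)),
        m_cov=np.array([random_spd(rng, L) / L for _ in range(M)]),
        T_dof=rng.random(M) * 3 + L,
        T_rate=np.array([random_spd(rng, L) for _ in range(M)]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def micro_instance(rng):
    """A small random (state, X, hyper) triple for update-equation tests."""
    N, D, L, M = 6, 5, 2, 3
    hyper = Hyperparameters(M=M, L=L)
    st = random_state(rng, N, D, L, M, hyper)
    X = rng.standard_normal((N, D)) * 2.0
    return st, X, hyper
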