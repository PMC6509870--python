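"""The VPAC probabilistic model and its coordinate-ascent variational inference.

The model projects each cell's expression vector ``x_n`` (length ``D``) onto a
latent vector ``z_n`` (length ``L``) through a linear map with isotropic
Gaussian noise,

    x_n | z_n ~ N(W z_n + mu, tau^-1 I_D),

while the latent vectors follow a Gaussian mixture with ``M`` components,

    z_n | s_n = j ~ N(m_j, T_j^-1),      s_n ~ Categorical(rho),

with conjugate priors everywhere: Gamma ARD precisions ``alpha_i`` on the
columns of ``W`` (large ``alpha_i`` switches column ``i`` off, selecting the
latent dimensionality automatically), a Gamma prior on the noise precision
``tau``, Gaussian priors on ``mu`` and the component means ``m_j``, Wishart
priors on the component precisions ``T_j`` and a Dirichlet prior on the
mixture weights ``rho``.

Inference is mean-field coordinate ascent (CAVI): each variational factor is
updated in closed form given the current moments of the others, and every
full sweep can only increase the evidence lower bound (ELBO). The posterior
over the component indicators (the "responsibilities") yields the hard
cluster labels.

Conventions fixed here (the factorisation is otherwise standard):

* ``Q(W)`` factorises over the ``D`` rows of ``W``; each row is an
  ``L``-vector with a single shared covariance ``Sigma_W`` (the only
  dimensionally consistent reading of the closed-form updates).
* The Wishart factors are parameterised by a degrees-of-freedom scalar and a
  *rate* (inverse-scale) matrix, so ``<T_j> = dof_j * rate_j^-1``; only this
  convention makes the additive scatter update conjugate.
* Expectations of log-determinants and log-weights use the exact digamma
  forms, and the noise-rate update uses the full posterior second moments of
  ``W``, ``z`` and ``mu``; both are required for a monotone ELBO.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.special import digamma, gammaln, multigammaln
from sklearn.cluster import KMeans

from .data import ExpressionMatrix, matrix_values
from .exceptions import ConfigurationError, NumericalError, ValidationError

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------

@dataclass
class Hyperparameters:
    """Fixed prior constants of the model.

    ``M`` (number of mixture components) and ``L`` (latent dimensionality)
    are the structural choices; all remaining scalars default to the broad
    setting 1e-3. ``delta`` defaults to the symmetric Dirichlet concentration
    ``1/M``; the Wishart prior defaults to the minimal proper degrees of
    freedom ``upsilon = L`` with identity rate matrix ``V``.
    """

    M: int
    L: int
    a_alpha: float = 1e-3
    b_alpha: float = 1e-3
    a_tau: float = 1e-3
    b_tau: float = 1e-3
    beta: float = 1e-3
    gamma: float = 1e-3
    delta: np.ndarray | None = None
    upsilon: float | None = None
    V: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.M = int(self.M)
        self.L = int(self.L)
        if self.M < 1:
            raise ConfigurationError(f"M must be >= 1, got {self.M}")
        if self.L < 1:
            raise ConfigurationError(f"L must be >= 1, got {self.L}")
        for name in ("a_alpha", "b_alpha", "a_tau", "b_tau", "beta", "gamma"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.delta is None:
            self.delta = np.full(self.M, 1.0 / self.M)
        else:
            self.delta = np.asarray(self.delta, dtype=np.float64)
            if self.delta.shape != (self.M,) or np.any(self.delta <= 0):
                raise ConfigurationError("delta must be a positive M-vector")
        if self.upsilon is None:
            self.upsilon = float(self.L)
        else:
            self.upsilon = float(self.upsilon)
            if self.upsilon < self.L:
                raise ConfigurationError("upsilon must be >= L")
        if self.V is None:
            self.V = np.eye(self.L)
        else:
            self.V = np.asarray(self.V, dtype=np.float64)
            if self.V.shape != (self.L, self.L):
                raise ConfigurationError("V must be L x L")
            if not np.allclose(self.V, self.V.T):
                raise ConfigurationError("V must be symmetric")
            try:
                np.linalg.cholesky(self.V)
            except np.linalg.LinAlgError as exc:
                raise ConfigurationError("V must be positive-definite") from exc


@dataclass
class VariationalState:
    """All factor parameters of the mean-field posterior.

    Shapes: ``N`` cells, ``D`` genes, ``L`` latent dimensions, ``M``
    components.
    """

    z_mean: np.ndarray        # (N, L)
    z_cov: np.ndarray         # (N, L, L)
    w_mean: np.ndarray        # (D, L) -- row d is the posterior mean of W's row d
    w_cov: np.ndarray         # (L, L) shared across rows
    mu_mean: np.ndarray       # (D,)
    mu_cov_scalar: float      # Sigma_mu = scalar * I
    alpha_shape: float
    alpha_rate: np.ndarray    # (L,)
    tau_shape: float
    tau_rate: float
    rho_conc: np.ndarray      # (M,)
    resp: np.ndarray          # (N, M) responsibilities, rows sum to 1
    m_mean: np.ndarray        # (M, L)
    m_cov: np.ndarray         # (M, L, L)
    T_dof: np.ndarray         # (M,)
    T_rate: np.ndarray        # (M, L, L)

    @property
    def n_cells(self) -> int:
        return self.z_mean.shape[0]

    @property
    def n_genes(self) -> int:
        return self.w_mean.shape[0]

    @property
    def n_latent(self) -> int:
        return self.z_mean.shape[1]

    @property
    def n_components(self) -> int:
        return self.resp.shape[1]

    def copy(self) -> "VariationalState":
        return replace(
            self,
            **{
                f.name: (v.copy() if isinstance(v := getattr(self, f.name), np.ndarray) else v)
                for f in self.__dataclass_fields__.values()
            },
        )


@dataclass
class FittedModel:
    """A converged variational state plus its optimisation trace."""

    state: VariationalState
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    hyper: Hyperparameters
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def latent(self) -> np.ndarray:
        """Posterior mean latent coordinates, ``(N, L)``."""
        return self.state.z_mean

    @property
    def alpha_mean(self) -> np.ndarray:
        """Posterior mean ARD precisions ``<alpha_i>``, ``(L,)``."""
        return self.state.alpha_shape / self.state.alpha_rate


class Moments(NamedTuple):
    """Posterior expectations consumed by the CAVI updates and the ELBO."""

    E_tau: float
    E_ln_tau: float
    E_alpha: np.ndarray       # (L,)
    E_ln_alpha: np.ndarray    # (L,)
    E_T: np.ndarray           # (M, L, L)
    E_ln_det_T: np.ndarray    # (M,)
    E_ln_rho: np.ndarray      # (M,)
    E_zzT: np.ndarray         # (N, L, L)
    E_WtW: np.ndarray         # (L, L)
    E_col_norm2: np.ndarray   # (L,)  <||W_i||^2> per column
    E_mmT: np.ndarray         # (M, L, L)
    E_mu_norm2: float


class EffectiveDimensionality(NamedTuple):
    count: int
    active: np.ndarray        # (L,) boolean flags
    recommended: int          # count + 1, the refit suggestion


# ---------------------------------------------------------------------------
# numerics helpers
# ---------------------------------------------------------------------------

def _symmetrize(A: np.ndarray) -> np.ndarray:
    return 0.5 * (A + np.swapaxes(A, -1, -2))


def _inv_spd(A: np.ndarray, context: str = "") -> np.ndarray:
    """Invert one or a stack of SPD matrices, with one jitter retry.

    Raises :class:`NumericalError` (naming the offending index for stacks)
    if a matrix is still not SPD after adding ``1e-8 * mean-diagonal`` jitter.
    """
    A = _symmetrize(np.asarray(A, dtype=np.float64))
    try:
        np.linalg.cholesky(A)
        return _symmetrize(np.linalg.inv(A))
    except np.linalg.LinAlgError:
        pass
    L = A.shape[-1]
    jitter = 1e-8 * np.trace(A, axis1=-2, axis2=-1)[..., None, None] / L
    A_j = A + jitter * np.eye(L)
    try:
        np.linalg.cholesky(A_j)
        return _symmetrize(np.linalg.inv(A_j))
    except np.linalg.LinAlgError:
        if A.ndim == 3:
            for idx in range(A.shape[0]):
                try:
                    np.linalg.cholesky(A_j[idx])
                except np.linalg.LinAlgError:
                    raise NumericalError(
                        f"matrix {idx} not positive-definite"
                        f"{' in ' + context if context else ''}"
                    ) from None
        raise NumericalError(
            f"matrix not positive-definite{' in ' + context if context else ''}"
        ) from None


def _ln_det_spd(A: np.ndarray) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        raise NumericalError("non-positive determinant of an SPD matrix")
    return logdet


# ---------------------------------------------------------------------------
# posterior moments
# ---------------------------------------------------------------------------

def expected_moments(state: VariationalState) -> Moments:
    """Assemble the posterior expectations the closed-form updates consume."""
    L = state.n_latent
    D = state.n_genes

    E_tau = state.tau_shape / state.tau_rate
    E_ln_tau = digamma(state.tau_shape) - np.log(state.tau_rate)
    E_alpha = state.alpha_shape / state.alpha_rate
    E_ln_alpha = digamma(state.alpha_shape) - np.log(state.alpha_rate)

    # Wishart with rate matrix: <T> = dof * rate^-1
    V_inv = _inv_spd(state.T_rate, context="T_rate")
    E_T = state.T_dof[:, None, None] * V_inv
    i = np.arange(1, L + 1)
    E_ln_det_T = (
        digamma(0.5 * (state.T_dof[:, None] + 1.0 - i)).sum(axis=1)
        + L * np.log(2.0)
        - _ln_det_spd(state.T_rate)
    )

    conc = state.rho_conc
    E_ln_rho = digamma(conc) - digamma(conc.sum())

    E_zzT = state.z_cov + np.einsum("na,nb->nab", state.z_mean, state.z_mean)
    E_WtW = state.w_mean.T @ state.w_mean + D * state.w_cov
    E_col_norm2 = np.sum(state.w_mean**2, axis=0) + D * np.diag(state.w_cov)
    E_mmT = state.m_cov + np.einsum("ja,jb->jab", state.m_mean, state.m_mean)
    E_mu_norm2 = float(np.sum(state.mu_mean**2) + D * state.mu_cov_scalar)

    return Moments(
        E_tau=float(E_tau),
        E_ln_tau=float(E_ln_tau),
        E_alpha=E_alpha,
        E_ln_alpha=E_ln_alpha,
        E_T=E_T,
        E_ln_det_T=E_ln_det_T,
        E_ln_rho=E_ln_rho,
        E_zzT=E_zzT,
        E_WtW=E_WtW,
        E_col_norm2=E_col_norm2,
        E_mmT=E_mmT,
        E_mu_norm2=E_mu_norm2,
    )


def _mixture_quadratic(state: VariationalState, mom: Moments) -> np.ndarray:
    """``Tr[<T_j>(<z_n z_n'> - <m_j><z_n>' - <z_n><m_j>' + <m_j m_j'>)]``.

    Returns an ``(N, M)`` array; shared by the responsibility update, the
    latent-prior ELBO term, and nothing else.
    """
    tr_Tzz = np.einsum("jab,nab->nj", mom.E_T, mom.E_zzT)
    Tm = np.einsum("jab,jb->ja", mom.E_T, state.m_mean)  # (M, L)
    cross = state.z_mean @ Tm.T                           # (N, M)
    tr_Tmm = np.einsum("jab,jab->j", mom.E_T, mom.E_mmT)  # (M,)
    return tr_Tzz - 2.0 * cross + tr_Tmm[None, :]


def _expected_residual(
    state: VariationalState, X: np.ndarray, mom: Moments
) -> float:
    """``sum_n E||x_n - W z_n - mu||^2`` under the current factors."""
    N = X.shape[0]
    pred = state.z_mean @ state.w_mean.T          # (N, D), <W><z_n>
    total = float(np.sum(X**2))
    total += N * mom.E_mu_norm2
    total += float(np.einsum("ab,nab->", mom.E_WtW, mom.E_zzT))
    total += 2.0 * float(np.sum(pred @ state.mu_mean))
    total -= 2.0 * float(np.sum(X * pred))
    total -= 2.0 * float(X.sum(axis=0) @ state.mu_mean)
    return total


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_state(
    X, hyper: Hyperparameters, seed: int = 0
) -> VariationalState:
    """Deterministic spectral initialisation of the variational state.

    ``w_mean`` is set to the top-``L`` principal directions of the centred
    data (sign-fixed so the largest-magnitude loading of each direction is
    positive), ``z_mean`` to the corresponding scores, and the
    responsibilities to a seeded k-means partition of the scores, floored at
    1e-6 and renormalised. All Gamma/Wishart/Dirichlet factors start at
    their priors; the component means start at the k-means centres.
    """
    Xv = matrix_values(X)
    N, D = Xv.shape
    M, L = hyper.M, hyper.L
    if L >= D:
        raise ConfigurationError(
            f"latent dimensionality L={L} must be < number of genes D={D}"
        )
    if M > N:
        raise ConfigurationError(f"M={M} clusters exceed N={N} cells")
    col_var = Xv.var(axis=0)
    if np.any(col_var <= 0):
        raise ValidationError(
            "zero-variance genes present; filter them before fitting"
        )

    mu0 = Xv.mean(axis=0)
    Xc = Xv - mu0
    # top-L principal directions and scores
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    directions = Vt[:L].T                      # (D, L), orthonormal
    # sign convention: largest-|loading| entry of each direction positive
    flip = np.sign(directions[np.abs(directions).argmax(axis=0), np.arange(L)])
    flip[flip == 0] = 1.0
    directions = directions * flip
    scores = Xc @ directions                   # (N, L)

    if M == 1:
        resp = np.ones((N, 1))
        centers = scores.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=M, n_init=10, random_state=int(seed))
        labels = km.fit_predict(scores)
        centers = km.cluster_centers_
        resp = np.full((N, M), 1e-6)
        resp[np.arange(N), labels] = 1.0 - (M - 1) * 1e-6

    return VariationalState(
        z_mean=scores,
        z_cov=np.broadcast_to(np.eye(L), (N, L, L)).copy(),
        w_mean=directions.copy(),
        w_cov=1e-3 * np.eye(L),
        mu_mean=mu0.copy(),
        mu_cov_scalar=1.0,
        alpha_shape=float(hyper.a_alpha),
        alpha_rate=np.full(L, float(hyper.b_alpha)),
        tau_shape=float(hyper.a_tau),
        tau_rate=float(hyper.b_tau),
        rho_conc=hyper.delta.copy(),
        resp=resp,
        m_mean=np.asarray(centers, dtype=np.float64).copy(),
        m_cov=np.broadcast_to(np.eye(L), (M, L, L)).copy(),
        T_dof=np.full(M, float(hyper.upsilon)),
        T_rate=np.broadcast_to(hyper.V, (M, L, L)).copy(),
    )


# ---------------------------------------------------------------------------
# CAVI updates (each mutates and returns the state)
# ---------------------------------------------------------------------------

def update_latent(
    state: VariationalState, X, hyper: Hyperparameters
) -> VariationalState:
    """Update ``Q(z_n)`` for every cell.

    ``Sigma_z^(n) = (<tau><W'W> + sum_j <s_jn><T_j>)^-1`` and
    ``m_z^(n) = Sigma_z^(n) (<tau><W>'(x_n - <mu>) + sum_j <s_jn><T_j><m_j>)``.
    """
    Xv = matrix_values(X)
    mom = expected_moments(state)
    prior_prec = np.einsum("nj,jab->nab", state.resp, mom.E_T)
    prec = mom.E_tau * mom.E_WtW + prior_prec           # (N, L, L)
    state.z_cov = _inv_spd(prec, context="update_latent")
    Tm = np.einsum("jab,jb->ja", mom.E_T, state.m_mean)  # (M, L)
    rhs = mom.E_tau * (Xv - state.mu_mean) @ state.w_mean + state.resp @ Tm
    state.z_mean = np.einsum("nab,nb->na", state.z_cov, rhs)
    return state


def update_projection(
    state: VariationalState, X, hyper: Hyperparameters
) -> VariationalState:
    """Update ``Q(W)``: shared row covariance and the D row means.

    ``Sigma_W = (diag(<alpha>) + <tau> sum_n <z_n z_n'>)^-1`` and row ``d``
    of ``w_mean`` equals ``<tau> Sigma_W sum_n <z_n>(x_nd - <mu_d>)``.
    """
    Xv = matrix_values(X)
    mom = expected_moments(state)
    prec = np.diag(mom.E_alpha) + mom.E_tau * mom.E_zzT.sum(axis=0)
    state.w_cov = _inv_spd(prec, context="update_projection")
    rhs = (Xv - state.mu_mean).T @ state.z_mean          # (D, L)
    state.w_mean = mom.E_tau * rhs @ state.w_cov
    return state


def update_offset(
    state: VariationalState, X, hyper: Hyperparameters
) -> VariationalState:
    """Update ``Q(mu)``: ``Sigma_mu = (beta + N<tau>)^-1 I`` and the mean."""
    Xv = matrix_values(X)
    N = Xv.shape[0]
    mom = expected_moments(state)
    state.mu_cov_scalar = 1.0 / (hyper.beta + N * mom.E_tau)
    resid = Xv - state.z_mean @ state.w_mean.T
    state.mu_mean = state.mu_cov_scalar * mom.E_tau * resid.sum(axis=0)
    return state


def update_ard(
    state: VariationalState, hyper: Hyperparameters
) -> VariationalState:
    """Update the ARD precisions: shape ``a_alpha + D/2``, rate
    ``b_alpha + <||W_i||^2>/2`` per column."""
    D = state.n_genes
    mom = expected_moments(state)
    state.alpha_shape = hyper.a_alpha + 0.5 * D
    state.alpha_rate = hyper.b_alpha + 0.5 * mom.E_col_norm2
    return state


def update_noise(
    state: VariationalState, X, hyper: Hyperparameters
) -> VariationalState:
    """Update ``Q(tau)``: shape ``a_tau + ND/2``, rate
    ``b_tau + (1/2) sum_n E||x_n - W z_n - mu||^2`` with full second
    moments of ``W``, ``z`` and ``mu``."""
    Xv = matrix_values(X)
    N, D = Xv.shape
    mom = expected_moments(state)
    state.tau_shape = hyper.a_tau + 0.5 * N * D
    rate = hyper.b_tau + 0.5 * _expected_residual(state, Xv, mom)
    if rate <= 0:
        raise NumericalError(f"noise rate became non-positive ({rate})")
    state.tau_rate = float(rate)
    return state


def update_responsibilities(state: VariationalState) -> VariationalState:
    """Update ``Q(s)`` in log space.

    ``ln P_jn = E[ln|T_j|]/2 + E[ln rho_j]
    - Tr[<T_j>(<z z'> - <m_j><z>' - <z><m_j>' + <m_j m_j'>)]/2``,
    normalised per cell with log-sum-exp.
    """
    mom = expected_moments(state)
    log_resp = (
        0.5 * mom.E_ln_det_T[None, :]
        + mom.E_ln_rho[None, :]
        - 0.5 * _mixture_quadratic(state, mom)
    )
    shift = log_resp.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(shift)):
        bad = int(np.flatnonzero(~np.isfinite(shift.ravel()))[0])
        raise NumericalError(f"responsibilities underflow for cell {bad}")
    p = np.exp(log_resp - shift)
    state.resp = p / p.sum(axis=1, keepdims=True)
    return state


def update_mixture_weights(
    state: VariationalState, hyper: Hyperparameters
) -> VariationalState:
    """Update ``Q(rho)``: concentration ``delta_j + sum_n <s_jn>``.

    The closed-form update adds the expected component counts to the prior
    concentration (the responsibilities stand in for the expectations of the
    binary indicators).
    """
    state.rho_conc = hyper.delta + state.resp.sum(axis=0)
    return state


def update_component_means(
    state: VariationalState, hyper: Hyperparameters
) -> VariationalState:
    """Update ``Q(m_j)``: ``Sigma_m^(j) = (gamma I + <T_j> sum_n <s_jn>)^-1``
    and ``m_m^(j) = Sigma_m^(j) <T_j> sum_n <s_jn><z_n>``."""
    L = state.n_latent
    mom = expected_moments(state)
    Nj = state.resp.sum(axis=0)                          # (M,)
    prec = hyper.gamma * np.eye(L) + Nj[:, None, None] * mom.E_T
    state.m_cov = _inv_spd(prec, context="update_component_means")
    weighted = state.resp.T @ state.z_mean               # (M, L)
    rhs = np.einsum("jab,jb->ja", mom.E_T, weighted)
    state.m_mean = np.einsum("jab,jb->ja", state.m_cov, rhs)
    return state


def update_component_precisions(
    state: VariationalState, hyper: Hyperparameters
) -> VariationalState:
    """Update ``Q(T_j)``: dof ``upsilon + sum_n <s_jn>`` and rate
    ``V + sum_n <s_jn>(<z z'> - <z><m_j>' - <m_j><z>' + <m_j m_j'>)``."""
    mom = expected_moments(state)
    Nj = state.resp.sum(axis=0)
    state.T_dof = hyper.upsilon + Nj
    Szz = np.einsum("nj,nab->jab", state.resp, mom.E_zzT)
    Sz = state.resp.T @ state.z_mean                     # (M, L)
    cross = np.einsum("ja,jb->jab", Sz, state.m_mean)
    rate = hyper.V + Szz - cross - np.swapaxes(cross, -1, -2)
    rate = rate + Nj[:, None, None] * mom.E_mmT
    state.T_rate = _symmetrize(rate)
    # SPD sanity: raise early if the scatter broke the rate matrix
    _inv_spd(state.T_rate, context="update_component_precisions")
    return state


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------

def _gamma_entropy(shape: float, rate: np.ndarray | float) -> np.ndarray | float:
    return shape - np.log(rate) + gammaln(shape) + (1.0 - shape) * digamma(shape)


def _wishart_ln_B(dof: np.ndarray, ln_det_rate: np.ndarray, L: int) -> np.ndarray:
    """Log normaliser of a Wishart in the rate parameterisation."""
    return (
        0.5 * dof * ln_det_rate
        - 0.5 * dof * L * np.log(2.0)
        - np.array([multigammaln(0.5 * d, L) for d in np.atleast_1d(dof)])
    )


def compute_elbo(state: VariationalState, X, hyper: Hyperparameters) -> float:
    """Evidence lower bound ``E_Q[ln P(X, theta)] - E_Q[ln Q(theta)]``.

    Expanded in closed form over the full joint; every full CAVI sweep must
    leave this non-decreasing (up to round-off).
    """
    Xv = matrix_values(X)
    N, D = Xv.shape
    L, M = hyper.L, hyper.M
    mom = expected_moments(state)

    # --- expected log joint ------------------------------------------------
    # likelihood
    e_lik = 0.5 * N * D * (mom.E_ln_tau - _LOG_2PI)
    e_lik -= 0.5 * mom.E_tau * _expected_residual(state, Xv, mom)

    # latent prior (Gaussian mixture)
    quad = _mixture_quadratic(state, mom)                # (N, M)
    e_z = float(
        np.sum(
            state.resp
            * (0.5 * mom.E_ln_det_T[None, :] - 0.5 * L * _LOG_2PI - 0.5 * quad)
        )
    )

    # indicators and mixture weights
    e_s = float(np.sum(state.resp * mom.E_ln_rho[None, :]))
    delta = hyper.delta
    e_rho = float(
        gammaln(delta.sum())
        - gammaln(delta).sum()
        + np.sum((delta - 1.0) * mom.E_ln_rho)
    )

    # component means and precisions
    E_m_norm2 = np.trace(state.m_cov, axis1=-2, axis2=-1) + np.sum(
        state.m_mean**2, axis=1
    )
    e_m = float(
        M * 0.5 * L * (np.log(hyper.gamma) - _LOG_2PI)
        - 0.5 * hyper.gamma * E_m_norm2.sum()
    )
    ln_det_V0 = float(_ln_det_spd(hyper.V))
    ln_B0 = float(
        0.5 * hyper.upsilon * ln_det_V0
        - 0.5 * hyper.upsilon * L * np.log(2.0)
        - multigammaln(0.5 * hyper.upsilon, L)
    )
    e_T = float(
        M * ln_B0
        + 0.5 * (hyper.upsilon - L - 1.0) * mom.E_ln_det_T.sum()
        - 0.5 * np.einsum("ab,jba->", hyper.V, mom.E_T)
    )

    # projection and its ARD prior
    e_W = float(
        np.sum(
            0.5 * D * (mom.E_ln_alpha - _LOG_2PI)
            - 0.5 * mom.E_alpha * mom.E_col_norm2
        )
    )
    e_alpha = float(
        np.sum(
            hyper.a_alpha * np.log(hyper.b_alpha)
            - gammaln(hyper.a_alpha)
            + (hyper.a_alpha - 1.0) * mom.E_ln_alpha
            - hyper.b_alpha * mom.E_alpha
        )
    )

    # offset and noise precision
    e_mu = (
        0.5 * D * (np.log(hyper.beta) - _LOG_2PI)
        - 0.5 * hyper.beta * mom.E_mu_norm2
    )
    e_tau = (
        hyper.a_tau * np.log(hyper.b_tau)
        - gammaln(hyper.a_tau)
        + (hyper.a_tau - 1.0) * mom.E_ln_tau
        - hyper.b_tau * mom.E_tau
    )

    # --- entropies ---------------------------------------------------------
    h_z = float(0.5 * _ln_det_spd(state.z_cov).sum() + 0.5 * N * L * (1.0 + _LOG_2PI))
    h_W = float(0.5 * D * _ln_det_spd(state.w_cov) + 0.5 * D * L * (1.0 + _LOG_2PI))
    h_mu = 0.5 * D * np.log(state.mu_cov_scalar) + 0.5 * D * (1.0 + _LOG_2PI)
    h_alpha = float(np.sum(_gamma_entropy(state.alpha_shape, state.alpha_rate)))
    h_tau = float(_gamma_entropy(state.tau_shape, state.tau_rate))

    conc = state.rho_conc
    c0 = conc.sum()
    h_rho = float(
        gammaln(conc).sum()
        - gammaln(c0)
        + (c0 - M) * digamma(c0)
        - np.sum((conc - 1.0) * digamma(conc))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(state.resp > 0, state.resp * np.log(state.resp), 0.0)
    h_s = float(-np.sum(plogp))
    h_m = float(
        0.5 * _ln_det_spd(state.m_cov).sum() + 0.5 * M * L * (1.0 + _LOG_2PI)
    )
    ln_det_VT = _ln_det_spd(state.T_rate)
    ln_B = _wishart_ln_B(state.T_dof, ln_det_VT, L)
    h_T = float(
        np.sum(
            -ln_B
            - 0.5 * (state.T_dof - L - 1.0) * mom.E_ln_det_T
            + 0.5 * state.T_dof * L
        )
    )

    terms = {
        "likelihood": e_lik,
        "latent": e_z,
        "indicators": e_s,
        "weights": e_rho,
        "means": e_m,
        "precisions": e_T,
        "projection": e_W,
        "ard": e_alpha,
        "offset": e_mu,
        "noise": e_tau,
        "H_z": h_z,
        "H_W": h_W,
        "H_mu": h_mu,
        "H_alpha": h_alpha,
        "H_tau": h_tau,
        "H_rho": h_rho,
        "H_s": h_s,
        "H_m": h_m,
        "H_T": h_T,
    }
    bad = [k for k, v in terms.items() if not np.isfinite(v)]
    if bad:
        raise NumericalError(f"non-finite ELBO terms: {', '.join(bad)}")
    return float(sum(terms.values()))


# ---------------------------------------------------------------------------
# fit loop and post-fit summaries
# ---------------------------------------------------------------------------

_SWEEP = (
    ("latent", update_latent, True),
    ("projection", update_projection, True),
    ("offset", update_offset, True),
    ("ard", lambda s, X, h: update_ard(s, h), False),
    ("noise", update_noise, True),
    ("responsibilities", lambda s, X, h: update_responsibilities(s), False),
    ("mixture_weights", lambda s, X, h: update_mixture_weights(s, h), False),
    ("component_means", lambda s, X, h: update_component_means(s, h), False),
    ("component_precisions", lambda s, X, h: update_component_precisions(s, h), False),
)


def cavi_sweep(state: VariationalState, X, hyper: Hyperparameters) -> VariationalState:
    """One full coordinate-ascent sweep over all factors, in a fixed order:
    latent -> projection -> offset -> ARD -> noise -> responsibilities ->
    mixture weights -> component means -> component precisions."""
    for _name, fn, _ in _SWEEP:
        state = fn(state, X, hyper)
    return state


def fit(
    X,
    hyper: Hyperparameters,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FittedModel:
    """Fit the model by CAVI until the relative ELBO change drops below
    ``tol`` or ``max_iter`` sweeps elapse.

    Deterministic given ``(X, hyper, seed)``: the only randomness is the
    seeded k-means used to initialise the responsibilities.
    """
    state = init_state(X, hyper, seed=seed)
    trace: list[float] = []
    converged = False
    prev = None
    for sweep_idx in range(1, max_iter + 1):
        try:
            state = cavi_sweep(state, X, hyper)
            elbo = compute_elbo(state, X, hyper)
        except NumericalError as exc:
            raise NumericalError(f"sweep {sweep_idx}: {exc}") from exc
        trace.append(elbo)
        if prev is not None and abs(elbo - prev) < tol * abs(prev):
            converged = True
            break
        prev = elbo
    cell_ids = X.cell_ids if isinstance(X, ExpressionMatrix) else [
        f"cell_{i}" for i in range(state.n_cells)
    ]
    gene_ids = X.gene_ids if isinstance(X, ExpressionMatrix) else [
        f"gene_{i}" for i in range(state.n_genes)
    ]
    return FittedModel(
        state=state,
        elbo_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
        seed=int(seed),
        hyper=hyper,
        cell_ids=list(cell_ids),
        gene_ids=list(gene_ids),
    )


def predict_labels(model: FittedModel | VariationalState) -> np.ndarray:
    """Hard cluster labels: argmax responsibility per cell, ties going to the
    smallest component index (numpy's argmax convention)."""
    state = model.state if isinstance(model, FittedModel) else model
    return np.argmax(state.resp, axis=1)


def gauge_fixed_alpha(model: FittedModel) -> np.ndarray:
    """ARD precisions in the unit-within-component-variance gauge.

    The model is invariant under rescaling latent dimension ``i`` by ``c``
    while scaling column ``i`` of ``W`` by ``1/c`` (the mixture means and
    precisions absorb the change), so raw ``<alpha_i>`` values are only
    comparable across dimensions after fixing this gauge. Here each column's
    second moment is rescaled by the responsibility-weighted within-component
    latent variance of its dimension — the model's own unit of latent scale —
    and the ARD rate recomputed. When ``<T_j> = I`` for all components this
    reduces to the raw ``<alpha_i>``.
    """
    state = model.state
    D = state.n_genes
    mom = expected_moments(state)
    covs = _inv_spd(mom.E_T, context="gauge_fixed_alpha")
    weights = state.resp.sum(axis=0) / state.n_cells
    within_var = np.einsum("j,jii->i", weights, covs)
    rate = model.hyper.b_alpha + 0.5 * within_var * mom.E_col_norm2
    return (model.hyper.a_alpha + 0.5 * D) / rate


def effective_dimensionality(
    model: FittedModel, ratio_threshold: float = 10.0
) -> EffectiveDimensionality:
    """Count the latent dimensions the ARD prior has kept switched on.

    Dimension ``i`` is active iff its (gauge-fixed, see
    :func:`gauge_fixed_alpha`) ARD precision satisfies ``alpha_i <=
    ratio_threshold * min_k alpha_k``; large precisions shrink their column
    of ``W`` to zero. The recommended refit dimensionality is ``count + 1``
    — one spare dimension tends to retain residual structure.
    """
    alpha = gauge_fixed_alpha(model)
    active = alpha <= ratio_threshold * alpha.min()
    count = int(active.sum())
    return EffectiveDimensionality(count=count, active=active, recommended=count + 1)
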