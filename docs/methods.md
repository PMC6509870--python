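# Methods

## Model

Each cell's expression vector `x_n ∈ R^D` is a noisy linear image of a
latent vector `z_n ∈ R^L`:

    x_n | z_n ~ N(W z_n + μ, τ⁻¹ I_D),

and the latent vectors follow an `M`-component Gaussian mixture

    z_n | s_n = j ~ N(m_j, T_j⁻¹),    P(s_n = j) = ρ_j.

This is probabilistic PCA with the isotropic latent prior replaced by a
mixture: dimensionality reduction and clustering share one likelihood, so
the projection is shaped by the cluster structure rather than fixed ahead
of it. Conjugate priors complete the specification: `ρ ~ Dir(δ)`,
`m_j ~ N(0, γ⁻¹I)`, `T_j ~ Wishart(υ, V)`, `μ ~ N(0, β⁻¹I)`,
`τ ~ Gamma(a_τ, b_τ)`, and independent ARD priors per projection column,
`W_i ~ N(0, α_i⁻¹ I_D)` with `α_i ~ Gamma(a_α, b_α)`.

Assumptions worth stating: the emission is Gaussian with a single isotropic
noise precision shared by all genes, so the model treats counts, TPM and
FPKM alike as real-valued observations and has no explicit zero-inflation
component; cells are exchangeable and independent given the parameters.

## Hyperparameters

| symbol | meaning | default | why |
|---|---|---|---|
| `M` | number of mixture components | required | the one structural choice the user must make |
| `L` | latent dimensionality | user-set (10 is a safe over-estimate) | ARD prunes unused columns, so only an upper bound is needed |
| `a_α, b_α, a_τ, b_τ, β, γ` | Gamma/Gaussian prior constants | `1e-3` | broad, data-dominated priors |
| `δ` | Dirichlet concentration | `1/M` per component | symmetric, lighter than add-one smoothing |
| `υ, V` | Wishart dof / rate matrix | `L`, `I_L` | minimal proper degrees of freedom, unit scale |
| `tol` | relative ELBO change to stop | `1e-6` | changes below this do not move labels in practice |
| `max_iter` | sweep cap | 500 | the separated regimes converge in 100–350 sweeps |

## Inference

The mean-field posterior factorises as
`Q(Z) Q(W) Q(μ) Q(α) Q(τ) Q(ρ) Q(s) Q(m) Q(T)` and is optimised by CAVI:
each factor's parameters are set to their exact conditional optimum given
the current moments of the others. One sweep updates, in order: latent
vectors → projection → offset → ARD precisions → noise precision →
responsibilities → mixture weights → component means → component
precisions. Any fixed order is valid coordinate ascent; this one refreshes
the projection arm before the mixture arm. The ELBO is evaluated in closed
form after every sweep and must never decrease — the test suite enforces
this within `|ELBO| · 1e-8` on every dataset it touches, which is the
single most sensitive end-to-end check of all update equations and moment
computations.

Three conventions pin down the algebra:

* **Row-wise `Q(W)`.** `Q(W)` is a product over the `D` rows of `W`, each
  an `L`-vector with one shared covariance `Σ_W ∈ R^{L×L}`. This is the
  only factorisation consistent with an `L×L` posterior covariance and a
  per-gene mean update, and it matches standard Bayesian-PCA structure.
* **Wishart in rate form.** `Q(T_j) = Wishart(υ_j, V_j)` with `V_j` a rate
  (inverse-scale) matrix, so `⟨T_j⟩ = υ_j V_j⁻¹` and the update
  accumulates the scatter additively onto `V`. Only this convention makes
  the additive update conjugate.
* **Exact expectations.** The responsibility update uses
  `E_q[ln|T_j|]` (multivariate digamma form) and `E_q[ln ρ_j]` (Dirichlet
  digamma), and the noise-rate update uses the full posterior second
  moments `E‖μ‖² = ‖m_μ‖² + D σ_μ`, `Tr(⟨WᵀW⟩⟨z_n z_nᵀ⟩)` and the
  factorised cross-terms. Substituting plug-in point values for any of
  these breaks ELBO monotonicity; a Monte-Carlo oracle in the tests
  verifies the noise rate is the true expectation.

### Initialisation

Deterministic given `(X, seed)`: `w_mean` is the top-`L` principal
directions of the centred data (sign-fixed on the largest loading),
`z_mean` the corresponding scores; responsibilities come from a seeded
k-means partition of the scores, floored at `1e-6` and renormalised;
component means start at the k-means centres; all Gamma, Wishart and
Dirichlet factors start at their priors. Spectral initialisation keeps
run-to-run variance low — two runs with the same seed produce bit-identical
ELBO traces.

### Numerical choices

Responsibilities are computed in log space with log-sum-exp. Every matrix
inverse goes through a symmetric-positive-definite check (Cholesky) with a
single retry after adding `1e-8 · mean-diagonal` jitter; failures raise a
`NumericalError` naming the offending factor and sweep. Scatter matrices
are symmetrised (`(A + Aᵀ)/2`) after accumulation. Ties in the hard label
argmax go to the smallest component index. Empty components are allowed
and simply revert toward their priors; `M` is never changed during a fit.
Zero-variance genes are rejected at fit entry (the preprocessing drops
them).

## Effective dimensionality and the latent gauge

A fitted column is "switched off" when its ARD precision `⟨α_i⟩` is large
and its norm near zero. The reported count applies a ratio rule — active
iff `α_i ≤ 10 · min_k α_k` — but to **gauge-fixed** precisions rather than
raw ones. The model is invariant under rescaling latent dimension `i` by
`c` while scaling column `i` of `W` by `1/c` (absorbed by `T_j` and `m_j`),
and under the broad `γ` prior the dimensions that carry cluster means drift
toward inflated latent scale and deflated `W` columns, which spreads raw
`⟨α_i⟩` across genuinely active columns by more than an order of
magnitude. Rescaling each column's second moment by the
responsibility-weighted within-component latent variance of its dimension
— the model's own unit of latent scale — removes the ambiguity; when
`⟨T_j⟩ = I` the adjusted precisions equal the raw ones. On data of true
rank `r ∈ {2, 3, 4}` fitted with `L = 10`, the gauge-fixed rule returns
exactly `r`; the raw rule does not. The recommended refit dimensionality is
`count + 1`: a spare dimension retains residual structure and tends to
score slightly better on real data.

## Synthetic data

The generator draws from the model itself: component labels from the
mixture weights, latent vectors from the component Gaussians, observations
through `W` plus isotropic noise. The reference regime ("easy preset") is
600 cells × 50 genes, three equally weighted components whose means sit at
pairwise latent distance `6√2 ≈ 8.5` (well beyond five latent standard
deviations, a regime where recovery should be essentially perfect),
identity component precisions, true latent rank 4 with orthogonal
projection columns of norms (5, 4, 3, 2), zero offset and noise precision
`τ = 10`. Rank presets reuse the regime with the column list truncated.
Values are model-space reals (negative entries allowed); a clamp-at-zero
flag produces sparse non-negative fixtures — clamping makes roughly half
the entries zero, a convenient stand-in for expression-like sparsity.

The dropout corruption zeroes an exact, uniformly chosen fraction of the
non-zero entries, mimicking transcript non-capture.

What the generator deliberately does **not** emulate: negative-binomial
count noise, library-size and batch effects, gene–gene correlation beyond
the low-rank structure, and biological zero-inflation. Passing the
recovery tests therefore demonstrates correctness of the inference on data
satisfying the model's assumptions, not state-of-the-art accuracy on real
scRNA-seq; on real data the Gaussian emission is an approximation the
user should be aware of (fitting raw counts, TPM or FPKM directly is the
intended usage, with an optional `log1p` flag available).

## Evaluation metrics

ARI and NMI are computed exactly from the contingency table: ARI with
integer binomial-coefficient sums (chance-corrected pair counting; when
the correction denominator is exactly zero the score is 1 for identical
partitions and 0 otherwise), NMI as `MI/√(H(C)H(T))` in natural logs with
`0·ln 0 = 0` and a score of 0 when either entropy vanishes. Both are
verified exhaustively against brute-force oracles on all partitions of up
to six items and against scikit-learn on random pairs.

## Problem sizes

The test and acceptance runs use 300–600 cells, 15–50 genes and up to ten
latent dimensions; at these sizes a full fit takes a few seconds and the
whole verification suite a couple of minutes. The implementation is dense
`O(N L²  + N D L)` per sweep and comfortably handles tens of thousands of
cells with a few thousand selected variable genes.

## Known limitations

* Single isotropic noise precision across genes; heavy-tailed or count
  noise is mis-modelled (no zero-inflation term).
* `M` is fixed; empty components are tolerated but never split or removed.
* The latent-scale gauge freedom means raw parameter values (e.g. `⟨α⟩`,
  `‖W_i‖`) are only interpretable after gauge fixing, as described above.
* CAVI finds a local optimum; the deterministic spectral + k-means
  initialisation makes runs reproducible but a pathological initialisation
  can still land in a poor basin on weakly separated data.
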