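"""Automatic selection of the latent dimensionality.

Generates data whose true latent rank is 3, deliberately over-fits with
L=8 latent dimensions, and shows how the ARD precisions switch off the
five unneeded projection columns.
"""

from vpac import (
    GenerativeConfig,
    Hyperparameters,
    column_importance,
    effective_dimensionality,
    fit,
    generate_dataset,
)

cfg = GenerativeConfig.rank_preset(r=3, seed=1, N=400, D=40)
X, _, _ = generate_dataset(cfg)

model = fit(X, Hyperparameters(M=3, L=8), seed=1)

print(column_importance(model).to_string(index=False))
# w_norm is each projection column's Euclidean norm; alpha_mean is the ARD
# precision that regularises it. Switched-off columns combine a near-zero
# norm with a precision orders of magnitude above the active ones.

eff = effective_dimensionality(model)
print(f"\nactive dimensions: {eff.count} (true rank {cfg.L_true})")
print(f"recommended refit dimensionality: {eff.recommended} "
      "(one spare dimension tends to help on real data)")
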