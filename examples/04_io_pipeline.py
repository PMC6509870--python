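"""Round-trip through the on-disk formats and the preprocessing steps.

Writes a sparse fixture in the 10x-style Matrix Market dialect, reads it
back, keeps the most variable genes and subsamples cells — the standard
path from a quantification directory to a fit-ready matrix.
"""

import tempfile
from pathlib import Path

import numpy as np

from vpac import (
    GenerativeConfig,
    MatrixSource,
    generate_dataset,
    read_matrix,
    select_top_variable_genes,
    subsample_cells,
    write_mtx,
)

cfg = GenerativeConfig.easy_preset(seed=3, N=200)
cfg.clamp_at_zero = True                     # expression-like: x >= 0
X, _, _ = generate_dataset(cfg)
print(f"fixture: {X.n_cells} cells x {X.n_genes} genes, "
      f"{np.mean(X.values == 0):.0%} zeros")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_mtx(X, tmp / "matrix.mtx", tmp / "genes.tsv", tmp / "barcodes.tsv")
    back = read_matrix(
        MatrixSource(path=tmp / "matrix.mtx", format="mtx",
                     genes_path=tmp / "genes.tsv",
                     barcodes_path=tmp / "barcodes.tsv")
    )
    print(f"round trip exact: {np.array_equal(back.values, X.values)}")

top = select_top_variable_genes(back, 20)
print(f"kept the {top.n_genes} most variable genes "
      f"(by per-gene standard deviation)")
sub = subsample_cells(top, fraction=0.5, seed=0)
print(f"subsampled to {sub.n_cells} cells (uniform, seeded, order kept)")
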