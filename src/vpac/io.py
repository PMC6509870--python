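"""Reading, preprocessing and writing expression matrices and model outputs.

Two input dialects are supported: dense delimited text (header row of gene
names, first column of cell identifiers) and the Matrix Market triplet
layout of 10x-style pipelines (``matrix.mtx`` stored genes x cells, with
gene and barcode sidecar files, one identifier per line).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import ExpressionMatrix
from .exceptions import FormatError, ValidationError
from .model import FittedModel


@dataclass
class MatrixSource:
    """Declaration of where and in which dialect a matrix lives.

    ``orientation`` states what the *rows of the file* contain; Matrix
    Market triplets default to the 10x convention of genes in rows, dense
    tables to cells in rows.
    """

    path: str | Path
    format: str = "dense"               # "dense" | "mtx"
    genes_path: str | Path | None = None
    barcodes_path: str | Path | None = None
    orientation: str | None = None      # "cells" | "genes" in rows

    def __post_init__(self) -> None:
        if self.format not in ("dense", "mtx"):
            raise FormatError(f"unknown format {self.format!r}")
        if self.orientation is None:
            self.orientation = "genes" if self.format == "mtx" else "cells"
        if self.orientation not in ("cells", "genes"):
            raise FormatError(f"unknown orientation {self.orientation!r}")
        if self.format == "mtx" and (
            self.genes_path is None or self.barcodes_path is None
        ):
            raise FormatError(
                "matrix-market input requires gene and barcode sidecar files"
            )


def _dedupe(names: list[str]) -> list[str]:
    """Disambiguate duplicate gene names with ``.1``, ``.2`` suffixes
    (10x gene lists contain duplicates)."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_matrix(source: MatrixSource | str | Path) -> ExpressionMatrix:
    """Read an expression matrix into the internal cells x genes layout."""
    if not isinstance(source, MatrixSource):
        source = MatrixSource(path=source)
    if source.format == "dense":
        return _read_dense(source)
    return _read_mtx(source)


def _read_dense(source: MatrixSource) -> ExpressionMatrix:
    path = Path(source.path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty matrix in {path}")
    values = df.to_numpy(dtype=np.float64)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if source.orientation == "genes":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    if np.any(values < 0):
        raise ValidationError(f"negative entries in {path}")
    return ExpressionMatrix(values, row_ids, _dedupe(col_ids))


def _read_sidecar(path: str | Path) -> list[str]:
    with open(path) as fh:
        # take the first tab-separated field of each line (10x gene files
        # carry id + symbol columns)
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_mtx(source: MatrixSource) -> ExpressionMatrix:
    path = Path(source.path)
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise FormatError(f"cannot parse Matrix Market file {path}: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat).toarray().astype(np.float64)
    genes = _read_sidecar(source.genes_path)
    barcodes = _read_sidecar(source.barcodes_path)
    if source.orientation == "genes":
        n_genes, n_cells = mat.shape
        mat = mat.T
    else:
        n_cells, n_genes = mat.shape
    if len(genes) != n_genes:
        raise FormatError(
            f"{source.genes_path}: {len(genes)} gene names for {n_genes} rows"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"{source.barcodes_path}: {len(barcodes)} barcodes for "
            f"{n_cells} columns"
        )
    if np.any(mat < 0):
        raise ValidationError(f"negative entries in {path}")
    return ExpressionMatrix(mat, barcodes, _dedupe(genes))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dense_tsv(X: ExpressionMatrix, path: str | Path) -> None:
    """Write cells x genes as TSV: header of gene names, first column
    ``cell_id``."""
    df = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_mtx(
    X: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write the genes x cells Matrix Market triplet dialect plus sidecars."""
    sparse = scipy.sparse.coo_matrix(X.values.T)
    scipy.io.mmwrite(str(matrix_path), sparse, precision=17)
    Path(genes_path).write_text("".join(g + "\n" for g in X.gene_ids))
    Path(barcodes_path).write_text("".join(c + "\n" for c in X.cell_ids))


def write_labels(cell_ids, labels, path: str | Path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "cluster": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (cell_id, label) TSV as a Series keyed by cell id."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cell_id, label)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def save_model(model: FittedModel, outdir: str | Path) -> None:
    """Serialise a fitted model as a directory of TSV/JSON files: hard
    labels, latent coordinates, projection means, ARD precisions, the ELBO
    trace and the run metadata."""
    from .model import predict_labels

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    st = model.state
    L = st.n_latent

    write_labels(model.cell_ids, predict_labels(model), outdir / "labels.tsv")

    latent = pd.DataFrame(
        st.z_mean, index=model.cell_ids, columns=[f"dim_{i}" for i in range(L)]
    )
    latent.index.name = "cell_id"
    latent.to_csv(outdir / "latent.tsv", sep="\t", float_format="%.10g")

    w = pd.DataFrame(
        st.w_mean, index=model.gene_ids, columns=[f"dim_{i}" for i in range(L)]
    )
    w.index.name = "gene_id"
    w.to_csv(outdir / "w_mean.tsv", sep="\t", float_format="%.10g")

    pd.DataFrame(
        {"dimension": np.arange(L), "alpha_mean": model.alpha_mean}
    ).to_csv(outdir / "alpha.tsv", sep="\t", index=False, float_format="%.10g")

    pd.DataFrame(
        {"sweep": np.arange(1, model.n_iter + 1), "elbo": model.elbo_trace}
    ).to_csv(outdir / "elbo.tsv", sep="\t", index=False, float_format="%.12g")

    meta = {
        "n_cells": st.n_cells,
        "n_genes": st.n_genes,
        "M": model.hyper.M,
        "L": model.hyper.L,
        "seed": model.seed,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "final_elbo": float(model.elbo_trace[-1]),
        "hyperparameters": {
            "a_alpha": model.hyper.a_alpha,
            "b_alpha": model.hyper.b_alpha,
            "a_tau": model.hyper.a_tau,
            "b_tau": model.hyper.b_tau,
            "beta": model.hyper.beta,
            "gamma": model.hyper.gamma,
            "delta": list(model.hyper.delta),
            "upsilon": model.hyper.upsilon,
        },
    }
    (outdir / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def select_top_variable_genes(X: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the ``k`` genes with largest standard deviation across cells.

    Standard deviations use the population divisor ``N``. Ties are broken by
    original gene order, zero-variance genes are always dropped (with a
    warning if that leaves fewer than ``k``), and the surviving genes keep
    their original column order.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    k = min(k, X.n_genes)
    sd = X.values.std(axis=0, ddof=0)
    order = np.argsort(-sd, kind="stable")       # descending, ties by position
    order = order[sd[order] > 0]
    if len(order) < k:
        warnings.warn(
            f"only {len(order)} genes with non-zero variance available "
            f"(requested {k})",
            stacklevel=2,
        )
        k = len(order)
    if k == 0:
        raise ValidationError("no genes with non-zero variance")
    keep = np.sort(order[:k])
    return X.subset_genes(keep)


def subsample_cells(X: ExpressionMatrix, fraction: float, seed: int) -> ExpressionMatrix:
    """Uniform subsample of ``round(fraction * N)`` cells without
    replacement, preserving cell order."""
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = int(round(fraction * X.n_cells))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(X.n_cells, size=n_keep, replace=False))
    return X.subset_cells(keep)


def log1p_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Optional ``log(1 + x)`` transform (off by default everywhere: the
    model is routinely fit on raw counts or TPM/FPKM directly)."""
    return ExpressionMatrix(
        np.log1p(X.values), list(X.cell_ids), list(X.gene_ids)
    )
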