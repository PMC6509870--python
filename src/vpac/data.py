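"""In-memory container for cells-by-genes expression matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError


@dataclass
class ExpressionMatrix:
    """A dense cells x genes expression matrix with identifiers.

    Values are UMI counts or continuous TPM/FPKM measurements; the model
    itself only assumes real-valued observations. By default entries must be
    non-negative (the convention of every expression quantification);
    model-space matrices drawn from the Gaussian generative process may set
    ``allow_negative`` since a linear-Gaussian emission can produce values
    below zero.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` array of finite expression values.
    cell_ids, gene_ids
        Identifiers for rows and columns; ``cell_ids`` must be unique.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    allow_negative: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise ValidationError(
                f"need at least 2 cells and 2 genes, got {n} x {d}"
            )
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} rows"
            )
        if len(self.gene_ids) != d:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {d} columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values")
        if not self.allow_negative and np.any(self.values < 0):
            raise ValidationError("negative expression values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix keeping the cells at ``index`` (in order)."""
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index],
            [self.cell_ids[i] for i in index],
            list(self.gene_ids),
            allow_negative=self.allow_negative,
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix keeping the genes at ``index`` (in order)."""
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[:, index],
            list(self.cell_ids),
            [self.gene_ids[i] for i in index],
            allow_negative=self.allow_negative,
        )


def matrix_values(X) -> np.ndarray:
    """Accept an :class:`ExpressionMatrix` or a raw array; return the array."""
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)
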