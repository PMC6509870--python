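"""Clustering agreement metrics computed from the contingency table.

Both metrics compare a predicted partition ``C`` against reference cell-type
labels ``T`` through the contingency counts ``n_ij`` (cells in cluster ``i``
and type ``j``) with marginals ``x_i``, ``y_j`` and total ``N``:

* ARI — the pair-counting Rand index corrected for chance,
  ``(sum_ij C(n_ij,2) - E) / (max - E)`` where
  ``E = sum_i C(x_i,2) * sum_j C(y_j,2) / C(N,2)`` and
  ``max = (sum_i C(x_i,2) + sum_j C(y_j,2)) / 2``.
* NMI — ``MI(C,T) / sqrt(H(C) H(T))`` with natural logarithms and the
  convention ``0 ln 0 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .exceptions import ValidationError


@dataclass
class ContingencyTable:
    """Joint label counts ``n_ij`` with their marginals."""

    counts: np.ndarray   # (K_C, K_T) integers
    row_sums: np.ndarray
    col_sums: np.ndarray
    total: int

    @classmethod
    def from_labels(cls, pred, truth) -> "ContingencyTable":
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        if pred.shape != truth.shape or pred.ndim != 1:
            raise ValidationError(
                f"label vectors must be 1-D and equal length, got shapes "
                f"{pred.shape} and {truth.shape}"
            )
        if pred.size < 2:
            raise ValidationError("need at least 2 samples")
        _, pi = np.unique(pred, return_inverse=True)
        _, ti = np.unique(truth, return_inverse=True)
        counts = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
        np.add.at(counts, (pi, ti), 1)
        return cls(
            counts=counts,
            row_sums=counts.sum(axis=1),
            col_sums=counts.sum(axis=0),
            total=int(counts.sum()),
        )


def _identical_partitions(table: ContingencyTable) -> bool:
    """True iff the two partitions coincide up to relabeling: every row and
    every column of the contingency table has exactly one non-zero block."""
    nz_rows = (table.counts > 0).sum(axis=1)
    nz_cols = (table.counts > 0).sum(axis=0)
    return bool(np.all(nz_rows == 1) and np.all(nz_cols == 1))


def adjusted_rand_index(pred, truth) -> float:
    """Chance-corrected pair-counting agreement between two partitions.

    Exact integer evaluation of the binomial-coefficient formula; 1.0 for
    identical partitions, ~0 for independent ones. When the denominator is
    exactly zero (both partitions all singletons, or both a single cluster)
    returns 1.0 if the partitions are identical and 0.0 otherwise.
    """
    table = ContingencyTable.from_labels(pred, truth)
    sum_ij = sum(comb(int(n), 2) for n in table.counts.ravel())
    sum_x = sum(comb(int(x), 2) for x in table.row_sums)
    sum_y = sum(comb(int(y), 2) for y in table.col_sums)
    pairs = comb(table.total, 2)
    expected = sum_x * sum_y / pairs
    max_index = 0.5 * (sum_x + sum_y)
    denom = max_index - expected
    if denom == 0:
        return 1.0 if _identical_partitions(table) else 0.0
    return float((sum_ij - expected) / denom)


def normalized_mutual_information(pred, truth) -> float:
    """``MI(C,T) / sqrt(H(C) H(T))`` in natural logs; 0 when either
    partition is a single cluster (zero entropy)."""
    table = ContingencyTable.from_labels(pred, truth)
    n = table.total
    p_ij = table.counts / n
    p_x = table.row_sums / n
    p_y = table.col_sums / n

    nz = table.counts > 0
    mi = float(
        np.sum(p_ij[nz] * np.log(p_ij[nz] / np.outer(p_x, p_y)[nz]))
    )
    h_x = float(-np.sum(p_x[p_x > 0] * np.log(p_x[p_x > 0])))
    h_y = float(-np.sum(p_y[p_y > 0] * np.log(p_y[p_y > 0])))
    if h_x == 0.0 or h_y == 0.0:
        return 0.0
    return mi / np.sqrt(h_x * h_y)
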