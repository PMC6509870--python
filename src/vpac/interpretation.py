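"""Post-fit interpretation: ARD diagnostics, signature genes, latent
separation and gene co-expression networks."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .exceptions import ValidationError
from .model import FittedModel


def column_importance(model: FittedModel) -> pd.DataFrame:
    """Per-latent-dimension importance of the projection matrix.

    Reports the Euclidean norm of each column of ``w_mean`` next to the
    posterior mean ARD precision ``<alpha_i>`` that governs it, ordered by
    importance (ascending ``<alpha_i>``: small precision = active column).
    """
    norms = np.linalg.norm(model.state.w_mean, axis=0)
    alpha = model.alpha_mean
    df = pd.DataFrame(
        {
            "dimension": np.arange(model.state.n_latent),
            "w_norm": norms,
            "alpha_mean": alpha,
        }
    )
    return df.sort_values("alpha_mean", kind="stable").reset_index(drop=True)


def top_signature_genes(
    model: FittedModel, dimension: int, k: int
) -> list[tuple[str, float]]:
    """The ``k`` genes with largest absolute weight in one projection
    column, descending; ties keep original gene order.

    A latent direction that isolates one cluster is a linear combination of
    genes, so its heaviest loadings are candidate marker genes for that
    cluster.
    """
    L = model.state.n_latent
    if not 0 <= dimension < L:
        raise ValidationError(f"dimension {dimension} out of range [0, {L})")
    if not 1 <= k <= model.state.n_genes:
        raise ValidationError(f"k={k} out of range [1, {model.state.n_genes}]")
    weights = np.abs(model.state.w_mean[:, dimension])
    order = np.argsort(-weights, kind="stable")[:k]
    return [(model.gene_ids[i], float(weights[i])) for i in order]


class LatentSeparation(NamedTuple):
    summary: pd.DataFrame      # per-cluster n / mean / std of the coordinate
    flagged_cluster: object    # cluster whose mean is most separated
    gap: float                 # its standardized gap from the pooled rest
    flagged: bool              # gap exceeds the threshold


def latent_separation(
    model: FittedModel,
    labels,
    dimension: int,
    gap_threshold: float = 3.0,
) -> LatentSeparation:
    """Summarise one latent coordinate per cluster and flag the cluster it
    singles out.

    For each cluster the standardized gap is ``|mean_c - mean_rest| /
    pooled_sd``; the cluster with the largest gap is flagged when the gap
    exceeds ``gap_threshold``.
    """
    labels = np.asarray(labels)
    z = model.state.z_mean[:, dimension]
    if labels.shape[0] != z.shape[0]:
        raise ValidationError("labels do not align with cells")
    uniq = np.unique(labels)
    rows = []
    gaps = {}
    for c in uniq:
        inside = z[labels == c]
        rest = z[labels != c]
        rows.append(
            {
                "cluster": c,
                "n": inside.size,
                "mean": float(inside.mean()),
                "std": float(inside.std(ddof=0)),
            }
        )
        if rest.size == 0:
            gaps[c] = 0.0
            continue
        pooled = np.sqrt(
            (inside.size * inside.var(ddof=0) + rest.size * rest.var(ddof=0))
            / (inside.size + rest.size)
        )
        gaps[c] = (
            abs(inside.mean() - rest.mean()) / pooled if pooled > 0 else 0.0
        )
    best = max(gaps, key=lambda c: gaps[c])
    return LatentSeparation(
        summary=pd.DataFrame(rows),
        flagged_cluster=best,
        gap=float(gaps[best]),
        flagged=bool(gaps[best] > gap_threshold),
    )


def coexpression_network(
    X: ExpressionMatrix, threshold: float = 0.4, absolute: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene co-expression network from pairwise Pearson correlation.

    An undirected edge joins every gene pair with ``PCC > threshold``
    (``|PCC| > threshold`` when ``absolute``); zero-variance genes are
    excluded (their correlation is undefined). Returns the edge list and
    the per-gene degree — the maximal-degree genes are the network hubs.
    Typically run on the cells of a single cluster to find genes
    co-ordinated within that cell population.
    """
    if X.n_cells < 3:
        raise ValidationError("need at least 3 cells for correlations")
    sd = X.values.std(axis=0, ddof=0)
    keep = np.flatnonzero(sd > 0)
    if keep.size == 0:
        raise ValidationError("all genes have zero variance")
    genes = [X.gene_ids[i] for i in keep]
    corr = np.corrcoef(X.values[:, keep], rowvar=False)
    corr = np.atleast_2d(corr)
    score = np.abs(corr) if absolute else corr

    iu, ju = np.triu_indices(len(keep), k=1)
    mask = score[iu, ju] > threshold
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in iu[mask]],
            "gene_b": [genes[j] for j in ju[mask]],
            "pcc": corr[iu[mask], ju[mask]],
        }
    )
    degree = pd.Series(0, index=pd.Index(genes, name="gene"), dtype=int)
    for col in ("gene_a", "gene_b"):
        counts = edges[col].value_counts()
        degree.loc[counts.index] += counts.astype(int)
    return edges, degree


def hub_genes(degree: pd.Series) -> list[str]:
    """Genes attaining the maximal degree of connectivity."""
    if degree.empty or degree.max() == 0:
        return []
    return list(degree.index[degree == degree.max()])
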