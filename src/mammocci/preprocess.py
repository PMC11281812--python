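"""Normalization, embedding, clustering and marker-based annotation.

Mirrors the standard scRNA-seq preprocessing route: depth normalization to a
fixed scale factor followed by log1p (natural log), PCA, Leiden community
detection on a k-nearest-neighbour graph in PC space, and cluster annotation
by argmax of mean marker-set expression. Annotation is optional — every
downstream module consumes only the metadata table, so datasets that arrive
with curated cell-type labels (as atlas subsets do) bypass this module
entirely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA, TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .datatypes import CountMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SCALE_FACTOR = 1e4


class ParameterError(ValueError):
    """An algorithm parameter is out of range for the given input."""


@dataclass
class NormalizedMatrix:
    """Log-normalized expression paired with its source counts.

    ``values[g, c] = log(1 + scale_factor * counts[g, c] / total_c)`` where
    ``total_c`` is cell *c*'s total count. The raw counts are kept so that
    fraction-expressing statistics stay normalization-invariant. Cells with
    zero total counts are excluded (flagged in ``dropped_cells``), never
    silently zeroed.
    """

    gene_symbols: list[str]
    cell_ids: list[str]
    values: sp.csr_matrix  # genes x cells, float
    counts: sp.csr_matrix  # genes x cells, int — same axes as values
    scale_factor: float
    dropped_cells: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_symbols)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass
class Embedding:
    """PCA embedding: cell coordinates, loadings, explained variance."""

    coords: np.ndarray  # cells x k
    loadings: np.ndarray  # k x genes, rows orthonormal
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def log_normalize(
    matrix: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """Depth-normalize each cell to ``scale_factor`` and apply log1p.

    Per-cell linear totals (``expm1`` of the values) equal ``scale_factor``
    exactly for every retained cell. Zero-total cells are dropped with a
    warning; an all-zero matrix raises.
    """
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be strictly positive")
    counts = matrix.counts.tocsc()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    keep = totals > 0
    if not keep.any():
        raise ValidationError("all cells have zero total counts")
    dropped = [c for c, k in zip(matrix.cell_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} zero-total cell(s): {dropped[:5]}",
            stacklevel=2,
        )
        counts = counts[:, keep]
        totals = totals[keep]
    cell_ids = [c for c, k in zip(matrix.cell_ids, keep) if k]
    values = counts.astype(np.float64).multiply(scale_factor / totals).tocsr()
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        gene_symbols=list(matrix.gene_symbols),
        cell_ids=cell_ids,
        values=values,
        counts=counts.tocsr(),
        scale_factor=float(scale_factor),
        dropped_cells=dropped,
    )


def pca(
    norm: NormalizedMatrix,
    k: int,
    center: bool = True,
    scale: bool = False,
    clip: float = 10.0,
    random_state: int = 0,
) -> Embedding:
    """PCA of cells in gene space (cells are observations).

    With ``scale=True`` each gene is standardized to unit variance (and
    clipped at ``clip`` standard deviations) before the decomposition, so
    highly abundant genes do not dominate the components.
    """
    max_k = min(norm.n_genes, norm.n_cells)
    if not (1 <= k <= max_k):
        raise ParameterError(f"k must be in [1, {max_k}], got {k}")
    x = np.asarray(norm.values.T.todense())
    if scale:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = np.clip((x - mu) / sd, -clip, clip)
    if center:
        model = PCA(
            n_components=k,
            svd_solver="full" if max_k <= 500 else "randomized",
            random_state=random_state,
        )
        coords = model.fit_transform(x)
        return Embedding(
            coords=coords,
            loadings=np.asarray(model.components_),
            explained_variance=np.asarray(model.explained_variance_),
            explained_variance_ratio=np.asarray(model.explained_variance_ratio_),
        )
    if k < max_k:
        model = TruncatedSVD(n_components=k, random_state=random_state)
        coords = model.fit_transform(x)
        return Embedding(
            coords=coords,
            loadings=np.asarray(model.components_),
            explained_variance=np.asarray(model.explained_variance_),
            explained_variance_ratio=np.asarray(model.explained_variance_ratio_),
        )
    # k == min(shape): full SVD of the uncentered matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    var = coords.var(axis=0)
    total_var = np.asarray(x).var(axis=0).sum()
    ratio = var / total_var if total_var > 0 else np.zeros(k)
    return Embedding(
        coords=coords,
        loadings=vt[:k],
        explained_variance=var,
        explained_variance_ratio=ratio,
    )


def cluster_cells(
    emb: Embedding,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on the kNN graph of the embedding.

    Returns one integer label per cell; deterministic for a fixed seed.
    """
    n = emb.coords.shape[0]
    if n < n_neighbors + 1:
        raise ParameterError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells, got {n}"
        )
    if resolution <= 0:
        raise ParameterError("resolution must be strictly positive")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb.coords)
    _, idx = nn.kneighbors(emb.coords)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:  # skip self
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def annotate_clusters(
    norm: NormalizedMatrix,
    clusters: np.ndarray,
    marker_sets: dict[str, tuple[str, ...]],
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each cluster the cell type whose markers score highest.

    The score of type *t* in cluster *c* is the mean over the cluster's
    cells of the mean normalized expression of *t*'s marker genes. Ties
    break to the lexicographically first type and are flagged low-confidence
    (margin 0). Returns per-cell type labels (indexed by cell id) and a
    per-cluster report with the winning score and its margin over the
    runner-up.
    """
    missing = sorted(
        {g for gs in marker_sets.values() for g in gs} - set(norm.gene_symbols)
    )
    if missing:
        raise ValidationError(f"marker genes absent from matrix: {missing}")
    clusters = np.asarray(clusters)
    if clusters.shape[0] != norm.n_cells:
        raise ValidationError("cluster labels do not match number of cells")

    types = sorted(marker_sets)
    # cells x types matrix of per-cell marker-set means
    scores = np.column_stack(
        [
            np.asarray(norm.values[norm.gene_index(marker_sets[t])].mean(axis=0)).ravel()
            for t in types
        ]
    )
    rows = []
    cell_type = np.empty(norm.n_cells, dtype=object)
    for c in np.unique(clusters):
        in_c = clusters == c
        mean_scores = scores[in_c].mean(axis=0)
        order = np.argsort(-mean_scores, kind="stable")  # stable => lexicographic ties
        best, second = order[0], (order[1] if len(order) > 1 else order[0])
        margin = float(mean_scores[best] - mean_scores[second])
        cell_type[in_c] = types[best]
        rows.append(
            {
                "cluster": int(c),
                "n_cells": int(in_c.sum()),
                "cell_type": types[best],
                "score": float(mean_scores[best]),
                "margin": margin,
                "low_confidence": bool(margin == 0.0),
            }
        )
    labels = pd.Series(cell_type, index=pd.Index(norm.cell_ids, name="cell_id"), name="cell_type")
    return labels, pd.DataFrame(rows)


def annotate(
    matrix: CountMatrix,
    marker_sets: dict[str, tuple[str, ...]],
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    n_pcs: int = 20,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[NormalizedMatrix, pd.DataFrame, pd.DataFrame]:
    """Full preprocessing convenience: normalize, embed, cluster, annotate.

    Returns the normalized matrix, a per-cell table (cell_id, cluster,
    cell_type) and the per-cluster annotation report.
    """
    norm = log_normalize(matrix, scale_factor)
    emb = pca(
        norm,
        k=min(n_pcs, min(norm.n_genes, norm.n_cells)),
        scale=True,
        random_state=seed,
    )
    clusters = cluster_cells(emb, n_neighbors=n_neighbors, resolution=resolution, seed=seed)
    labels, report = annotate_clusters(norm, clusters, marker_sets)
    cells = pd.DataFrame(
        {"cell_id": norm.cell_ids, "cluster": clusters, "cell_type": labels.values}
    )
    return norm, cells, report
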