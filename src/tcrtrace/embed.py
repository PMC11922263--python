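"""Marker-weighted PCA, KNN graph, modularity clustering, pseudobulk means.

T cells are transcriptionally homogeneous enough that an unweighted PCA of
variable genes mixes compartments within clusters. The embedding here
up-weights a panel of immune marker genes before the SVD so the components
capture compartment and maturation structure: each scaled feature column is
multiplied by its weight (default 1), then the top principal components are
taken from a singular-value decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)


def select_variable_genes(Xnorm, var_names, n: int = 400) -> list[str]:
    """The ``n`` genes with the highest variance of normalized expression.

    Ties at the selection boundary break toward the gene earlier in input
    order (stable sort), so the result is deterministic.
    """
    var_names = list(var_names)
    if n > len(var_names):
        raise ValueError(f"asked for {n} variable genes but only {len(var_names)} genes present")
    A = np.asarray(Xnorm.todense()) if sparse.issparse(Xnorm) else np.asarray(Xnorm)
    v = A.var(axis=0, ddof=1) if A.shape[0] > 1 else np.zeros(A.shape[1])
    order = np.argsort(-v, kind="stable")
    return [var_names[i] for i in order[:n]]


@dataclass
class Embedding:
    """PC scores plus the decomposition bookkeeping.

    ``scores`` is cells x n_pcs; ``loadings`` feature x n_pcs; signs follow
    the convention that each component's largest-magnitude loading is
    positive, making scores reproducible across runs and cell orderings.
    """

    scores: np.ndarray
    loadings: np.ndarray
    singular_values: np.ndarray
    variance_ratio: np.ndarray
    feature_names: list
    weights: np.ndarray


def weighted_pca(
    Xscaled: np.ndarray,
    feature_names,
    weights: dict | None = None,
    n_pcs: int = 10,
    default_weight: float = 1.0,
) -> Embedding:
    """PCA of the scaled matrix after multiplying each feature by its weight.

    ``Xscaled`` is cells x features, already gene-centered, restricted to the
    feature set (union of weighted markers and selected variable genes). A
    weight of 0 removes a gene's influence entirely; unit weights reduce to
    ordinary PCA.
    """
    feature_names = list(feature_names)
    if len(feature_names) == 0:
        raise ValueError("empty feature set")
    A = np.asarray(Xscaled, dtype=np.float64)
    if A.shape[1] != len(feature_names):
        raise ValueError("feature_names length does not match matrix width")
    w = np.array([(weights or {}).get(g, default_weight) for g in feature_names], float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    n_pcs = int(n_pcs)
    if n_pcs < 1 or n_pcs > min(A.shape):
        raise ValueError(f"n_pcs={n_pcs} out of range for matrix {A.shape}")
    W = A * w
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    total = float((S**2).sum())
    return Embedding(
        scores=U[:, :n_pcs] * S[:n_pcs],
        loadings=Vt[:n_pcs].T,
        singular_values=S[:n_pcs],
        variance_ratio=(S[:n_pcs] ** 2) / total if total > 0 else np.zeros(n_pcs),
        feature_names=feature_names,
        weights=w,
    )


def knn_graph(scores: np.ndarray, k: int = 20) -> igraph.Graph:
    """Undirected k-nearest-neighbour graph in PC space, symmetrized by union.

    Each cell is linked to its ``k`` Euclidean nearest neighbours (self
    excluded); an edge exists if either endpoint selected the other.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    edges = set()
    for i in range(n):
        neigh = [int(j) for j in idx[i] if j != i][:k]
        for j in neigh:
            edges.add((i, j) if i < j else (j, i))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    log.info("knn graph: %d cells, %d edges (k=%d)", n, g.ecount(), k)
    return g


def cluster_graph(graph: igraph.Graph, resolution: float = 1.5, seed: int = 0) -> np.ndarray:
    """Modularity-based community detection (Leiden, a Louvain-family
    optimizer of the RB-configuration objective) at the given resolution.

    Deterministic given ``seed``. Labels are consecutive integers ordered by
    decreasing cluster size (ties: smaller original community id first), so
    label 0 is always the largest cluster.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    sizes = np.bincount(membership)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    relabel = np.empty(sizes.size, dtype=int)
    relabel[order] = np.arange(sizes.size)
    labels = relabel[membership]
    log.info("clustering: %d clusters at resolution %.2f", sizes.size, resolution)
    return labels


def modularity_brute_force(graph: igraph.Graph, resolution: float = 1.0) -> list[set]:
    """Exhaustively maximize the (RB-configuration) modularity over all
    partitions; tractable only for <= ~12 nodes. Test oracle for
    :func:`cluster_graph`."""
    n = graph.vcount()
    if n > 12:
        raise ValueError("brute force limited to 12 nodes")
    best, best_q = None, -np.inf
    for assignment in _set_partitions(list(range(n))):
        membership = np.empty(n, int)
        for ci, block in enumerate(assignment):
            for v in block:
                membership[v] = ci
        q = leidenalg.RBConfigurationVertexPartition(
            graph, initial_membership=list(membership), resolution_parameter=resolution
        ).quality()
        if q > best_q + 1e-12:
            best_q, best = q, [set(b) for b in assignment]
    return best


def _set_partitions(items: list):
    """All partitions of a list (restricted-growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def pseudobulk(Xnorm, var_names, labels) -> pd.DataFrame:
    """Mean normalized expression per cluster per gene (clusters x genes)."""
    labels = pd.Series(np.asarray(labels), name="cluster")
    if labels.isna().any():
        raise ValueError("every cell must be labelled")
    A = np.asarray(Xnorm.todense()) if sparse.issparse(Xnorm) else np.asarray(Xnorm)
    df = pd.DataFrame(A, columns=list(var_names))
    df["cluster"] = labels.to_numpy()
    return df.groupby("cluster", observed=True).mean()
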