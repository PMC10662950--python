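"""Shared-nearest-neighbor graph construction and modularity clustering.

Cells are embedded in a k-nearest-neighbor graph on Euclidean distance in
the reduced (PC) space; the SNN graph reweights cell pairs by the Jaccard
similarity of their kNN sets (each set includes the cell itself) and prunes
weak edges.  Communities are found by modularity optimization (Leiden by
default for seeded determinism, classic Louvain optionally).
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import Embedding

__all__ = ["SNNGraph", "build_snn", "cluster_cells"]


@dataclass
class SNNGraph:
    """Weighted undirected SNN graph over cells.

    ``weights`` is a symmetric sparse matrix of Jaccard similarities in
    (0, 1] with no self-edges.
    """

    weights: sp.csr_matrix
    cell_ids: pd.Index
    k: int
    dims: int
    prune: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_igraph(self) -> ig.Graph:
        coo = sp.triu(self.weights, k=1).tocoo()
        g = ig.Graph(
            n=self.n_cells,
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"weight": coo.data.tolist()},
        )
        return g

    def edge_table(self) -> pd.DataFrame:
        coo = sp.triu(self.weights, k=1).tocoo()
        return pd.DataFrame(
            {
                "cell_a": self.cell_ids[coo.row],
                "cell_b": self.cell_ids[coo.col],
                "weight": coo.data,
            }
        )


def _knn_sets(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest cells (self included), ties broken by cell index."""
    n = coords.shape[0]
    # Full pairwise distances: adequate at the cell counts this package
    # targets, and allows an exact stable tie-break by cell index.
    sq = np.sum(coords**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * coords @ coords.T
    np.fill_diagonal(d2, -1.0)  # the cell itself always ranks first
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def build_snn(
    emb: Embedding, dims: int = 20, k: int = 20, prune: float = 1 / 15
) -> SNNGraph:
    """Build the Jaccard SNN graph from the first ``dims`` embedding components.

    Edge weight = |N(i) & N(j)| / |N(i) | N(j)| over kNN sets that include
    the cell itself; edges with weight <= ``prune`` are removed.
    """
    if dims > emb.n_components:
        raise ValueError(f"dims={dims} exceeds available components {emb.n_components}")
    n = len(emb.cell_ids)
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells {n}")
    nbrs = _knn_sets(emb.coords[:, :dims], k)
    rows = np.repeat(np.arange(n), k)
    B = sp.csr_matrix(
        (np.ones(n * k, dtype=np.int32), (rows, nbrs.ravel())), shape=(n, n)
    )
    inter = (B @ B.T).toarray().astype(float)
    union = 2.0 * k - inter
    with np.errstate(invalid="ignore"):
        jac = inter / union
    np.fill_diagonal(jac, 0.0)
    jac[jac <= prune] = 0.0
    W = sp.csr_matrix(jac)
    return SNNGraph(weights=W, cell_ids=emb.cell_ids, k=k, dims=dims, prune=prune)


def cluster_cells(
    snn: SNNGraph,
    resolution: float = 0.8,
    seed: int = 0,
    method: str = "leiden",
) -> pd.Series:
    """Partition the SNN graph by modularity optimization.

    ``method`` is ``"leiden"`` (default; deterministic under ``seed``) or
    ``"louvain"`` (igraph multilevel).  Cluster ids are dense integers from
    0, ordered by decreasing cluster size with first-cell order breaking
    ties; singleton components become their own clusters.
    """
    if snn.n_cells == 0:
        raise ValueError("SNN graph is empty")
    g = snn.to_igraph()
    weights = g.es["weight"] if g.ecount() else None
    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        membership = np.asarray(part.membership)
    elif method == "louvain":
        import random

        state = ig.Graph.community_multilevel
        ig.set_random_number_generator(random.Random(seed))
        try:
            part = g.community_multilevel(weights=weights, resolution=resolution)
        finally:
            ig.set_random_number_generator(random)
        membership = np.asarray(part.membership)
        del state
    else:
        raise ValueError(f"unknown method {method!r}; use 'leiden' or 'louvain'")

    # Relabel to dense ids ordered by (size desc, first cell index).
    ids, first = np.unique(membership, return_index=True)
    sizes = np.array([(membership == i).sum() for i in ids])
    order = np.lexsort((first, -sizes))
    remap = {int(ids[j]): rank for rank, j in enumerate(order)}
    labels = np.array([remap[int(m)] for m in membership])
    return pd.Series(labels, index=snn.cell_ids, name="cluster")
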