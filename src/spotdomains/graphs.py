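"""Spatial neighbor network (SNN) construction and cell-type-aware pruning.

The SNN links spots within a distance radius (strict ``< r``) or by
symmetrized k-nearest-neighbor membership, always with self-loops. The
cell-type-aware variant (ctaSNN) removes every edge whose endpoints fall in
different expression-only preclusters (Louvain on PCA of the normalized
matrix), so attention never mixes unrelated cell populations across a
tissue boundary.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data_io import SpotDataset


@dataclass
class NeighborGraph:
    """Sparse symmetric binary adjacency over spots, self-loops included."""

    adjacency: sp.csr_matrix
    kind: str                      # "radius" | "knn"
    param: float
    has_self_loops: bool = True
    pruned_with: str | None = None

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def edge_arrays(self):
        """Canonical (dst, src) arrays: one entry per A[i, j] = 1, meaning
        j is a neighbor of i (j in S_i). Row-major order, deterministic."""
        coo = self.adjacency.tocoo()
        order = np.lexsort((coo.col, coo.row))
        return coo.row[order], coo.col[order]

    def neighbor_check(self):
        A = self.adjacency
        if (A != A.T).nnz != 0:
            raise AssertionError("adjacency is not symmetric")
        if self.has_self_loops and not np.all(A.diagonal() == 1):
            raise AssertionError("missing self-loops")


def _finite_coords(coords):
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return coords


def build_radius_graph(coords, rad_cutoff: float) -> NeighborGraph:
    """A[i, j] = 1 iff Euclidean distance(i, j) < rad_cutoff; plus loops."""
    coords = _finite_coords(coords)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots")
    if rad_cutoff <= 0:
        raise ValueError("rad_cutoff must be positive")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(rad_cutoff, output_type="ndarray")
    # query_pairs uses <=; enforce the strict "< r" rule
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < rad_cutoff]
    rows = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(n)])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(n)])
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A.data[:] = 1.0
    return NeighborGraph(A, kind="radius", param=float(rad_cutoff))


def build_knn_graph(coords, k: int = 6) -> NeighborGraph:
    """Directed k-NN by Euclidean distance, symmetrized by union, + loops.

    Distance ties resolve to the lower spot index (stable lexicographic
    ordering on (distance, index)).
    """
    coords = _finite_coords(coords)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} outside [1, {n - 1}]")
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2) \
        if n <= 2048 else None
    rows, cols = [], []
    if dist is not None:
        for i in range(n):
            d = dist[i].copy()
            d[i] = np.inf
            order = np.lexsort((np.arange(n), d))[:k]
            rows.append(np.full(k, i))
            cols.append(order)
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        for i in range(n):
            sel = [j for j in idx[i] if j != i][:k]
            rows.append(np.full(len(sel), i))
            cols.append(np.asarray(sel))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)  # union symmetrization
    A = A + sp.eye(n, format="csr")
    A.data[:] = 1.0
    return NeighborGraph(A.tocsr(), kind="knn", param=float(k))


def precluster_expression(ds: SpotDataset, resolution: float = 1.0,
                          seed: int = 0, n_pcs: int = 30,
                          n_neighbors: int = 15) -> np.ndarray:
    """Expression-only Louvain preclusters for ctaSNN pruning.

    PCA (``n_pcs`` components, reduced with a warning when fewer spots are
    available), 15-NN graph, Louvain communities. Deterministic given seed.
    """
    if not ds.normalized:
        raise ValueError("precluster_expression expects normalized data")
    n = ds.n_spots
    if np.allclose(ds.X, ds.X[0]):  # no structure: one community
        return np.zeros(n, dtype=int)
    max_pcs = min(n - 1, ds.n_genes)
    if n_pcs > max_pcs:
        import logging
        logging.getLogger("spotdomains").warning(
            "reducing PCA components from %d to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    Z = PCA(n_components=n_pcs, random_state=seed).fit_transform(ds.X)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(Z)
    _, idx = nn.kneighbors(Z)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i] if i != j}
    g = ig.Graph(n=n, edges=sorted(edges))
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def prune_to_ctasnn(graph: NeighborGraph, labels) -> NeighborGraph:
    """Remove every non-loop edge whose endpoints differ in precluster."""
    labels = np.asarray(labels)
    if labels.shape != (graph.n,):
        raise ValueError("label length does not match graph size")
    coo = graph.adjacency.tocoo()
    keep = (labels[coo.row] == labels[coo.col]) | (coo.row == coo.col)
    A = sp.csr_matrix(
        (np.ones(int(keep.sum())), (coo.row[keep], coo.col[keep])),
        shape=(graph.n, graph.n))
    fp = hashlib.sha1(labels.astype(np.int64).tobytes()).hexdigest()[:12]
    return NeighborGraph(A, kind=graph.kind, param=graph.param,
                         pruned_with=fp)


def write_edgelist(graph: NeighborGraph, path) -> None:
    dst, src = graph.edge_arrays()
    pd.DataFrame({"i": dst, "j": src}).to_csv(path, sep="\t", index=False)


def read_edgelist(path, n: int) -> NeighborGraph:
    df = pd.read_csv(path, sep="\t")
    A = sp.csr_matrix((np.ones(len(df)), (df["i"], df["j"])), shape=(n, n))
    return NeighborGraph(A, kind="knn", param=float("nan"),
                         has_self_loops=bool(np.all(A.diagonal() == 1)))
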