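"""Final spatial-domain calling on the learned embeddings.

Louvain/Leiden community detection on a 15-NN graph of the embedding, or a
full-covariance Gaussian mixture (the model-based route, equivalent in
spirit to mclust), plus resolution tuning toward a target number of domains
and a single-pass neighborhood majority-vote refinement over the tissue
coordinates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

DEFAULT_R_REFINE = 50.0


@dataclass
class DomainAssignment:
    labels: np.ndarray
    method: str
    param: float
    refined: bool = False
    r_refine: float | None = None
    exact_k: bool = True


def _contiguous(labels) -> np.ndarray:
    """Relabel to 0-based contiguous ids in order of first appearance."""
    labels = np.asarray(labels, dtype=int)
    _, first = np.unique(labels, return_index=True)
    mapping = {labels[i]: rank for rank, i in enumerate(sorted(first))}
    return np.array([mapping[l] for l in labels], dtype=int)


def _embedding_graph(Z, n_neighbors: int = 15) -> ig.Graph:
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(Z)
    _, idx = nn.kneighbors(Z)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i] if j != i}
    return ig.Graph(n=n, edges=sorted(edges))


def cluster_embeddings(Z, method: str, param, seed: int = 0
                       ) -> DomainAssignment:
    """Cluster embedding rows.

    method "louvain"/"leiden": 15-NN graph at resolution ``param``;
    method "gmm": full-covariance Gaussian mixture with ``param``
    components, k-means initialization. Deterministic given seed.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if method == "louvain":
        g = _embedding_graph(Z)
        ig.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(resolution=float(param))
        labels = np.asarray(part.membership)
    elif method == "leiden":
        g = _embedding_graph(Z)
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(param), seed=seed, n_iterations=2)
        labels = np.asarray(part.membership)
    elif method == "gmm":
        gm = GaussianMixture(n_components=int(param), covariance_type="full",
                             init_params="kmeans", n_init=10,
                             random_state=seed, reg_covar=1e-5)
        labels = gm.fit_predict(Z)
    else:
        raise ValueError(f"unknown clustering method: {method!r}")
    return DomainAssignment(_contiguous(labels), method, float(param))


def tune_resolution(Z, method: str, target_k: int, seed: int = 0,
                    lo: float = 0.05, hi: float = 5.0, max_evals: int = 60
                    ) -> DomainAssignment:
    """Bisection on the resolution until exactly ``target_k`` communities.

    Falls back to the closest achieved k (flagged ``exact_k=False``) when
    the target is never hit within ``max_evals`` evaluations.
    """
    if method not in ("louvain", "leiden"):
        raise ValueError("resolution tuning applies to louvain/leiden only")
    Z = np.asarray(Z, dtype=np.float64)
    if target_k < 2:
        raise ValueError("target_k must be at least 2")
    if target_k > Z.shape[0]:
        raise ValueError("target_k exceeds the number of spots")

    best, best_gap = None, np.inf

    def attempt(res):
        nonlocal best, best_gap
        assign = cluster_embeddings(Z, method, res, seed=seed)
        k = assign.labels.max() + 1
        gap = abs(k - target_k)
        if gap < best_gap:
            best, best_gap = assign, gap
        return k, assign

    k_lo, a = attempt(lo)
    if k_lo == target_k:
        return a
    k_hi, a = attempt(hi)
    if k_hi == target_k:
        return a
    evals = 2
    lo_, hi_ = lo, hi
    while evals < max_evals and hi_ - lo_ > 1e-4:
        mid = 0.5 * (lo_ + hi_)
        k_mid, a = attempt(mid)
        evals += 1
        if k_mid == target_k:
            return a
        if k_mid < target_k:
            lo_ = mid
        else:
            hi_ = mid
    best.exact_k = False
    return best


def refine_by_neighborhood(labels, coords, r_refine: float = DEFAULT_R_REFINE
                           ) -> np.ndarray:
    """One simultaneous pass of spatial majority voting.

    Each spot is reassigned to the most frequent label among the spots
    within ``r_refine`` of it (itself excluded), all votes computed from
    the pre-refinement labels. Ties keep the spot's own label if it is
    among the winners, else take the lowest label id. Isolated spots keep
    their label.
    """
    labels = np.asarray(labels, dtype=int)
    coords = np.asarray(coords, dtype=np.float64)
    if r_refine <= 0:
        raise ValueError("r_refine must be positive")
    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r_refine)
    out = labels.copy()
    for i, neigh in enumerate(neighbor_lists):
        neigh = [j for j in neigh if j != i]
        if not neigh:
            continue
        counts = np.bincount(labels[neigh])
        winners = np.flatnonzero(counts == counts.max())
        out[i] = labels[i] if labels[i] in winners else winners[0]
    return out
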