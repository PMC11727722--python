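"""Clustering validity indices: ARI, Davies-Bouldin, Calinski-Harabasz,
and S_Dbw (Halkidi & Vazirgiannis 2001 variant).

ARI compares two labelings; the other three score a labeling against the
embedding geometry (lower DB, higher CH, lower S_Dbw = better). All four
are implemented from their standard definitions; the tests pin them to
independent second implementations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import comb


@dataclass
class MetricsReport:
    db: float
    ch: float
    s_dbw: float
    ari: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index via the contingency-table form.

    ARI = (RI - E[RI]) / (max RI - E[RI]); 1 iff the partitions agree up
    to relabeling, ~0 for independent labelings.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings have different lengths")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 elements")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)
    sum_ij = comb(cont, 2).sum()
    sum_a = comb(cont.sum(axis=1), 2).sum()
    sum_b = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _groups(Z, labels):
    Z = np.asarray(Z, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    idx = [np.flatnonzero(labels == u) for u in uniq]
    cents = np.array([Z[i].mean(axis=0) for i in idx])
    return Z, uniq, idx, cents


def davies_bouldin(Z, labels) -> float:
    """DB = mean over clusters of max_{j != i} (s_i + s_j) / d_ij, with
    s_i the mean distance to the centroid and d_ij the centroid distance."""
    Z, uniq, idx, cents = _groups(Z, labels)
    k = len(uniq)
    s = np.array([np.linalg.norm(Z[i] - c, axis=1).mean()
                  for i, c in zip(idx, cents)])
    db = 0.0
    for i in range(k):
        worst = -np.inf
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            if d == 0:
                raise ValueError(
                    f"coincident centroids for clusters {uniq[i]} and "
                    f"{uniq[j]}")
            worst = max(worst, (s[i] + s[j]) / d)
        db += worst
    return float(db / k)


def calinski_harabasz(Z, labels) -> float:
    """CH = [B/(k-1)] / [W/(n-k)] with between- and within-cluster
    scatter B and W."""
    Z, uniq, idx, cents = _groups(Z, labels)
    n, k = Z.shape[0], len(uniq)
    if k >= n:
        raise ValueError("need k < n")
    grand = Z.mean(axis=0)
    B = sum(len(i) * float(((c - grand) ** 2).sum())
            for i, c in zip(idx, cents))
    W = sum(float(((Z[i] - c) ** 2).sum()) for i, c in zip(idx, cents))
    if W == 0:
        raise ValueError("degenerate within-cluster scatter")
    return float((B / (k - 1)) / (W / (n - k)))


def s_dbw(Z, labels) -> float:
    """S_Dbw = Scat + Dens_bw.

    Scat averages the ratio of per-cluster to global variance-vector
    norms. Dens_bw compares the point density at cluster-pair midpoints
    to the density at the two centroids, counting points within a radius
    equal to the average cluster standard deviation
    (stdev = (1/k) * sqrt(sum_i ||sigma(c_i)||)).
    """
    Z, uniq, idx, cents = _groups(Z, labels)
    k = len(uniq)
    sigma_all = Z.var(axis=0)
    norm_all = np.linalg.norm(sigma_all)
    if norm_all == 0:
        raise ValueError("zero global variance")
    sigma_i = [Z[i].var(axis=0) for i in idx]
    norms_i = np.array([np.linalg.norm(s) for s in sigma_i])
    scat = float(norms_i.mean() / norm_all)
    stdev = np.sqrt(norms_i.sum()) / k

    def density(u, members):
        if stdev == 0:
            return 0
        d = np.linalg.norm(Z[members] - u, axis=1)
        return int((d <= stdev).sum())

    dens = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            members = np.concatenate([idx[i], idx[j]])
            mid = 0.5 * (cents[i] + cents[j])
            denom = max(density(cents[i], members),
                        density(cents[j], members))
            if denom > 0:
                dens += density(mid, members) / denom
    dens_bw = dens / (k * (k - 1))
    return float(scat + dens_bw)


def evaluate(Z, labels, truth=None) -> MetricsReport:
    """All internal indices on (Z, labels), plus ARI when truth is given."""
    rep = MetricsReport(
        db=davies_bouldin(Z, labels),
        ch=calinski_harabasz(Z, labels),
        s_dbw=s_dbw(Z, labels),
    )
    if truth is not None:
        rep.ari = adjusted_rand_index(truth, labels)
    return rep
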