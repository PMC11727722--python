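"""Multiscale deep subspace clustering on the encoder's per-layer embeddings.

Each encoder layer k contributes a self-expression matrix C_k (zero
diagonal, so no spot trivially explains itself) minimizing
||Z_k - C_k Z_k||_F^2: under the union-of-subspaces assumption a spot's
embedding is a linear combination of the other spots in its subspace. The
per-layer matrices are fused with trainable positive weights tau_k into
C_F, symmetrized into an affinity Lambda = (|C_F| + |C_F^T|) / 2, and
spectrally clustered.

The memory cost is O(L * n^2); a hard cap refuses n > 20,000 spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from ._autodiff import Adam, Tensor

MAX_SPOTS = 20_000


@dataclass
class SubspaceState:
    """Trained self-expression matrices and the derived clustering."""

    C: list[np.ndarray]
    tau: np.ndarray
    C_F: np.ndarray
    Lambda: np.ndarray
    Y_clu: np.ndarray | None
    m: int
    norm_p: str = "fro"


def _check_diag(C_list):
    for k, C in enumerate(C_list):
        if np.any(np.diagonal(C) != 0):
            raise ValueError(f"C[{k}] has a nonzero diagonal")


def self_expression_loss(Z_list, C_list) -> float:
    """L_mss = 1/(2L) * sum_k ||Z_k - C_k Z_k||_F^2."""
    if len(Z_list) != len(C_list):
        raise ValueError("Z_list and C_list length mismatch")
    _check_diag(C_list)
    L = len(Z_list)
    total = sum(float(((Z - C @ Z) ** 2).sum())
                for Z, C in zip(Z_list, C_list))
    return total / (2.0 * L)


def coefficient_regularization(C_list, norm_p: str = "fro") -> float:
    """L_reg = 1/L * sum_k ||C_k||_p; p in {"fro", "l1"}."""
    _check_diag(C_list)
    if norm_p == "fro":
        norms = [float(np.sqrt((C ** 2).sum())) for C in C_list]
    elif norm_p == "l1":
        norms = [float(np.abs(C).sum()) for C in C_list]
    else:
        raise ValueError(f"unknown norm: {norm_p!r}")
    return sum(norms) / len(C_list)


def fuse_coefficients(C_list, tau) -> np.ndarray:
    """C_F = sum_k tau_k C_k / sum_k tau_k (convex combination)."""
    tau = np.asarray(tau, dtype=np.float64)
    if np.any(tau <= 0):
        raise ValueError("fusion weights must be positive")
    num = sum(t * C for t, C in zip(tau, C_list))
    return num / tau.sum()


def build_affinity(C_F) -> np.ndarray:
    """Lambda = (|C_F| + |C_F^T|) / 2: symmetric, non-negative."""
    C_F = np.asarray(C_F, dtype=np.float64)
    if C_F.shape[0] != C_F.shape[1]:
        raise ValueError("C_F must be square")
    return 0.5 * (np.abs(C_F) + np.abs(C_F.T))


def fit_self_expression(Z_list, beta: float = 1.0, norm_p: str = "fro_sq",
                        epochs: int = 2000, lr: float = 1e-2, seed: int = 0,
                        m: int | None = None, hook=None) -> SubspaceState:
    """Train the self-expression matrices on frozen embeddings.

    Minimizes 1/(2L) sum_k ||Z_k - C_k Z_k||_F^2 + beta/L sum_k ||C_k||_p
    with the diagonal hard-masked to zero. ``norm_p`` "fro_sq" uses the
    squared Frobenius norm (smooth ridge; admits a closed-form solution
    per row), "fro" the plain norm, "l1" the entrywise l1. When ``m`` is
    given the affinity is spectrally clustered into m groups. ``hook``
    (epoch, state) runs every epoch for instrumentation.
    """
    Z_list = [np.asarray(Z, dtype=np.float64) for Z in Z_list]
    n = Z_list[0].shape[0]
    if n > MAX_SPOTS:
        raise ValueError(f"n={n} exceeds the O(n^2) memory cap of "
                         f"{MAX_SPOTS} spots")
    L = len(Z_list)
    rng = np.random.default_rng(seed)
    Zt = [Tensor(Z) for Z in Z_list]
    C_raw = [Tensor(rng.uniform(-1e-4, 1e-4, (n, n)), requires_grad=True)
             for _ in range(L)]
    mask = Tensor(1.0 - np.eye(n))
    tau_raw = Tensor(np.full(L, np.log(np.e - 1.0)), requires_grad=True)
    opt = Adam([*C_raw, tau_raw], lr=lr)

    def current_state(with_labels=False):
        Cm = [c.data * mask.data for c in C_raw]
        tau = np.log1p(np.exp(tau_raw.data))
        C_F = fuse_coefficients(Cm, tau)
        Lam = build_affinity(C_F)
        y = spectral_cluster(Lam, m, seed=seed) \
            if (with_labels and m is not None) else None
        return SubspaceState(C=Cm, tau=tau, C_F=C_F, Lambda=Lam, Y_clu=y,
                             m=m or 0, norm_p=norm_p)

    for epoch in range(epochs):
        loss = None
        for k in range(L):
            Cm = C_raw[k] * mask
            term = (Zt[k] - Cm @ Zt[k]).sumsq() * (1.0 / (2.0 * L))
            if norm_p == "fro_sq":
                reg = Cm.sumsq() * (beta / L)
            elif norm_p == "fro":
                reg = Cm.frob() * (beta / L)
            elif norm_p == "l1":
                reg = Cm.abs().sum() * (beta / L)
            else:
                raise ValueError(f"unknown norm: {norm_p!r}")
            term = term + reg
            loss = term if loss is None else loss + term
        opt.zero_grad()
        loss.backward()
        opt.step()
        if hook is not None:
            hook(epoch, current_state())
    return current_state(with_labels=True)


def lsr_self_expression(Z, beta: float) -> np.ndarray:
    """Closed form of min_C 1/2 ||Z - CZ||_F^2 + beta ||C||_F^2 with
    diag(C) = 0, via the least-squares-regression identity: with
    D = (Z Z^T + 2 beta I)^{-1}, the solution is C_ij = -D_ji / D_ii for
    i != j. One O(n^3) inverse; used to warm-start the self-expression
    matrices so the decoder's input swap to C_F Z_L starts from a
    self-expressive C instead of noise."""
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    if beta <= 0:
        raise ValueError("beta must be positive")
    D = np.linalg.inv(Z @ Z.T + 2.0 * beta * np.eye(n))
    C = -(D / np.diag(D)[None, :]).T
    np.fill_diagonal(C, 0.0)
    return C


def solve_self_expression_ridge(Z, beta: float) -> np.ndarray:
    """Closed form of min_C 1/2 ||Z - CZ||_F^2 + beta ||C||_F^2,
    diag(C) = 0: each row of C is a ridge regression of z_i on the other
    rows (direct reference solution for small n)."""
    Z = np.asarray(Z, dtype=np.float64)
    n = Z.shape[0]
    C = np.zeros((n, n))
    for i in range(n):
        others = np.delete(np.arange(n), i)
        G = Z[others] @ Z[others].T + 2.0 * beta * np.eye(n - 1)
        C[i, others] = np.linalg.solve(G, Z[others] @ Z[i])
    return C


def spectral_cluster(Lambda, m: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering of a symmetric affinity.

    Symmetric normalized Laplacian, the m eigenvectors of its smallest
    eigenvalues, row-normalization, then k-means (n_init=10, seeded).
    """
    Lambda = np.asarray(Lambda, dtype=np.float64)
    n = Lambda.shape[0]
    if m < 2:
        raise ValueError("need at least 2 clusters")
    if m > n:
        raise ValueError("more clusters than points")
    deg = Lambda.sum(axis=1)
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    Lsym = np.eye(n) - (dinv[:, None] * Lambda) * dinv[None, :]
    Lsym = 0.5 * (Lsym + Lsym.T)  # exact symmetry for eigh
    vals, vecs = scipy.linalg.eigh(Lsym, subset_by_index=(0, m - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    U = vecs / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=m, n_init=10, random_state=seed)
    return km.fit_predict(U).astype(int)
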