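"""Weight-tied graph attention autoencoder (GATE) over the spot graph.

Encoder layer k < L aggregates neighbor messages with learned edge
attention:

    h_i^(k) = ELU( sum_{j in S_i} att_ij^(k) * W_k h_j^(k-1) )

with attention logits e_ij = sigmoid(v_s . W_k h_i + v_r . W_k h_j)
softmax-normalized over each neighborhood S_i (self-loop included). The
final encoder layer is a plain linear map + ELU. The decoder reuses the
encoder weights transposed and the same attention values — tying halves the
parameter count and regularizes the reconstruction. A mixing weight
``alpha`` blends attention computed on the plain spatial graph with
attention restricted to the cell-type-aware graph.

All math runs on the package's autodiff tape; the public functions accept
and return plain numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, edge_aggregate, segment_softmax
from .graphs import NeighborGraph

DEFAULT_HIDDEN_DIMS = (512, 30)


@dataclass
class GateModel:
    """Parameters of the tied-weight graph attention autoencoder.

    ``layer_dims`` is ``[n_genes, *hidden]`` (default hidden (512, 30));
    layers 1..L-1 carry attention vectors ``v_s``/``v_r``; the decoder has
    no parameters of its own.
    """

    layer_dims: list[int]
    alpha: float = 0.0
    W: list[Tensor] = field(default_factory=list)
    v_s: list[Tensor] = field(default_factory=list)
    v_r: list[Tensor] = field(default_factory=list)
    _att_cache: list | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")

    @classmethod
    def create(cls, n_genes: int, hidden_dims=DEFAULT_HIDDEN_DIMS,
               alpha: float = 0.0, rng=None) -> "GateModel":
        rng = np.random.default_rng(rng)
        dims = [int(n_genes), *map(int, hidden_dims)]
        model = cls(layer_dims=dims, alpha=alpha)
        for k in range(len(dims) - 1):
            d_in, d_out = dims[k], dims[k + 1]
            bound = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
            model.W.append(Tensor(rng.uniform(-bound, bound, (d_in, d_out)),
                                  requires_grad=True))
            if k < len(dims) - 2:  # attention only on layers 1..L-1
                model.v_s.append(Tensor(rng.uniform(-0.1, 0.1, d_out),
                                        requires_grad=True))
                model.v_r.append(Tensor(rng.uniform(-0.1, 0.1, d_out),
                                        requires_grad=True))
        return model

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims) - 1

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.v_s, *self.v_r]

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


@dataclass
class EmbeddingSet:
    """Per-layer embeddings Z_k (k = 1..L) and the reconstruction."""

    Z: list[np.ndarray]
    X_hat: np.ndarray | None = None


def _attention_t(H_prev: Tensor, W: Tensor, v_s: Tensor, v_r: Tensor,
                 graph: NeighborGraph):
    """Edge attention on ``graph``: returns (att Tensor, dst, src, HW)."""
    dst, src = graph.edge_arrays()
    deg = np.bincount(dst, minlength=graph.n)
    if np.any(deg == 0):
        raise ValueError("node without neighbors or self-loop: softmax "
                         "over an empty set")
    HW = H_prev @ W
    s = HW @ v_s
    r = HW @ v_r
    e = (s.take(dst) + r.take(src)).sigmoid()
    att = segment_softmax(e, dst, graph.n)
    return att, dst, src, HW


def compute_attention(H_prev, W, v_s, v_r, graph: NeighborGraph):
    """Numpy-facing attention: (dst, src, att) aligned edge arrays.

    ``att[e]`` is the normalized weight of neighbor ``src[e]`` in the
    neighborhood of ``dst[e]``; each neighborhood sums to 1.
    """
    att, dst, src, _ = _attention_t(Tensor(H_prev), Tensor(W), Tensor(v_s),
                                    Tensor(v_r), graph)
    return dst, src, att.data.copy()


def combine_attention(att_spatial, att_aware, alpha: float):
    """Convex blend (1 - alpha) * spatial + alpha * aware, no renorm.

    ``att_aware`` must already live on the spatial edge set, with zeros on
    the pruned edges.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if isinstance(att_spatial, Tensor) or isinstance(att_aware, Tensor):
        return att_spatial * (1.0 - alpha) + att_aware * alpha
    return (1.0 - alpha) * np.asarray(att_spatial) \
        + alpha * np.asarray(att_aware)


def _cta_edge_positions(snn: NeighborGraph, ctasnn: NeighborGraph):
    """Index of each ctaSNN edge inside the SNN edge arrays."""
    dst, src = snn.edge_arrays()
    cdst, csrc = ctasnn.edge_arrays()
    n = snn.n
    lookup = {d * n + s: p for p, (d, s) in enumerate(zip(dst, src))}
    try:
        return np.array([lookup[d * n + s] for d, s in zip(cdst, csrc)],
                        dtype=int)
    except KeyError:
        raise ValueError("ctaSNN has an edge absent from the SNN") from None


def _encode_t(Xt: Tensor, model: GateModel, snn: NeighborGraph,
              ctasnn: NeighborGraph | None):
    """Tape-building encoder. Caches per-layer attention on the model."""
    if Xt.shape[1] != model.layer_dims[0]:
        raise ValueError(f"input has {Xt.shape[1]} genes, model expects "
                         f"{model.layer_dims[0]}")
    dst, src = snn.edge_arrays()
    n = snn.n
    cta_pos = None
    if ctasnn is not None and model.alpha > 0.0:
        cta_pos = _cta_edge_positions(snn, ctasnn)
    H = Xt
    Z, att_cache = [], []
    L = model.n_layers
    for k in range(L - 1):
        att_sp, _, _, HW = _attention_t(H, model.W[k], model.v_s[k],
                                        model.v_r[k], snn)
        if cta_pos is not None:
            att_cta, cdst, csrc, _ = _attention_t(
                H, model.W[k], model.v_s[k], model.v_r[k], ctasnn)
            att_aw = att_cta.scatter_to(cta_pos, len(dst))
            att = combine_attention(att_sp, att_aw, model.alpha)
        else:
            att = att_sp
        H = edge_aggregate(att, HW, src, dst, n).elu()
        Z.append(H)
        att_cache.append(att)
    H = (H @ model.W[L - 1]).elu()  # final layer: plain linear + ELU
    Z.append(H)
    model._att_cache = att_cache
    return Z


def _decode_t(Ht: Tensor, model: GateModel, snn: NeighborGraph):
    """Tape-building decoder mirroring the encoder with W_k^T and the
    attention values cached by the last encoder pass."""
    if model._att_cache is None:
        raise RuntimeError("decode requires a preceding encode pass "
                           "(attention is shared with the encoder)")
    dst, src = snn.edge_arrays()
    n = snn.n
    L = model.n_layers
    H = Ht
    for k in range(L - 1, 0, -1):  # attention layers, transposed weights
        att = model._att_cache[k - 1]
        H = edge_aggregate(att, H @ model.W[k].T, src, dst, n).elu()
    return H @ model.W[0].T  # output layer: identity activation


def encode(X, snn: NeighborGraph, ctasnn: NeighborGraph | None,
           model: GateModel) -> EmbeddingSet:
    """Forward pass of the encoder; returns all per-layer embeddings."""
    Z = _encode_t(Tensor(np.asarray(X, dtype=np.float64)), model, snn, ctasnn)
    return EmbeddingSet(Z=[z.data.copy() for z in Z])


def decode(Z_or_CZ, model: GateModel, snn: NeighborGraph) -> np.ndarray:
    """Decode an embedding (Z_L while pretraining, C_F Z_L afterwards)."""
    return _decode_t(Tensor(np.asarray(Z_or_CZ, dtype=np.float64)),
                     model, snn).data.copy()


def reconstruction_loss(X, X_hat) -> float:
    """L_att = 1/2 * ||X - X_hat||_F^2 (residual sum of squares)."""
    X, X_hat = np.asarray(X), np.asarray(X_hat)
    if X.shape != X_hat.shape:
        raise ValueError("shape mismatch")
    return 0.5 * float(((X - X_hat) ** 2).sum())


def gate_total_loss(L_att: float, W_list, wd_coeff: float = 1.0) -> float:
    """L_1 = L_att + wd_coeff * 1/2 * sum_k ||W_k||_F^2 over encoder
    layers 1..L-1 (the attention layers)."""
    pen = sum(float((np.asarray(W if not isinstance(W, Tensor) else W.data)
                     ** 2).sum()) for W in W_list)
    return float(L_att) + wd_coeff * 0.5 * pen
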