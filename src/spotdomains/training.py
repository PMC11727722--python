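"""Self-supervised joint training of the autoencoder and subspace module.

Schedule: a pretraining phase minimizes the reconstruction objective L_1
alone (decoder fed Z_L directly); a joint phase then feeds the decoder the
self-expressed embedding C_F Z_L and minimizes

    L_total = L_1 + L_reg + lambda * L_mss + L_sup

where L_sup is the cross-entropy between a small classifier head on Z_L and
the current spectral-clustering labels Y_clu, refreshed from the affinity
matrix every ``refresh_every`` epochs. The clustering labels thus act as a
self-supervision signal that sharpens the embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import subspace as sub
from ._autodiff import Adam, Tensor
from .data_io import SpotDataset
from .gate import GateModel, EmbeddingSet, _decode_t, _encode_t
from .graphs import NeighborGraph

logger = logging.getLogger("spotdomains")

DEFAULT_HEAD_DIMS = (128, 64, 32)


@dataclass
class ClassifierHead:
    """Classifier mapping Z_L to m domain probabilities.

    Four linear maps d_L -> D1 -> D2 -> D3 -> m with ReLU between and a
    row softmax at the end (the three hidden fully connected layers plus
    the output projection).
    """

    dims: list[int]
    W: list[Tensor] = field(default_factory=list)
    b: list[Tensor] = field(default_factory=list)

    @classmethod
    def create(cls, d_in: int, m: int, hidden=DEFAULT_HEAD_DIMS, rng=None
               ) -> "ClassifierHead":
        rng = np.random.default_rng(rng)
        dims = [int(d_in), *map(int, hidden), int(m)]
        head = cls(dims=dims)
        for a, bdim in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / (a + bdim))
            head.W.append(Tensor(rng.uniform(-bound, bound, (a, bdim)),
                                 requires_grad=True))
            head.b.append(Tensor(np.zeros(bdim), requires_grad=True))
        return head

    @property
    def m(self) -> int:
        return self.dims[-1]

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.b]

    def forward_t(self, Z: Tensor) -> Tensor:
        H = Z
        for k in range(len(self.W) - 1):
            H = (H @ self.W[k] + self.b[k]).relu()
        logits = H @ self.W[-1] + self.b[-1]
        shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant
        e = (logits - shift).exp()
        return e / e.sum_rows()


def classify_spots(Z_L, head: ClassifierHead) -> np.ndarray:
    """Row-stochastic class probabilities P (n × m)."""
    Z_L = np.asarray(Z_L, dtype=np.float64)
    if Z_L.shape[1] != head.dims[0]:
        raise ValueError("embedding dimension does not match head input")
    return head.forward_t(Tensor(Z_L)).data.copy()


def self_supervised_loss(P, y, reduction: str = "mean") -> float:
    """Cross-entropy -1/n sum_i log P(i, y_i) with clipped probabilities."""
    P = np.asarray(P, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if np.any(y < 0) or np.any(y >= P.shape[1]):
        raise ValueError("labels outside [0, m)")
    picked = np.clip(P[np.arange(len(y)), y], 1e-12, 1.0)
    total = -np.log(picked).sum()
    return float(total / len(y)) if reduction == "mean" else float(total)


@dataclass
class LossReport:
    """Per-epoch bookkeeping of every loss term."""

    epoch: int
    phase: str
    L_att: float
    L_1: float
    L_mss: float
    L_reg: float
    L_sup: float
    lam: float
    total: float

    @property
    def L_2(self) -> float:
        return self.L_mss + self.L_reg


def total_loss(parts: dict, lam: float) -> LossReport:
    """Compose the total objective from its parts (pure bookkeeping)."""
    total = parts["L_1"] + parts["L_reg"] + lam * parts["L_mss"] \
        + parts["L_sup"]
    return LossReport(epoch=parts.get("epoch", -1),
                      phase=parts.get("phase", ""),
                      L_att=parts["L_att"], L_1=parts["L_1"],
                      L_mss=parts["L_mss"], L_reg=parts["L_reg"],
                      L_sup=parts["L_sup"], lam=lam, total=total)


@dataclass
class TrainConfig:
    """Knobs of the full training schedule (all deterministic given seed)."""

    m: int                              # number of subspace clusters
    alpha: float = 0.0                  # SNN vs ctaSNN attention mix
    lam: float = 0.1                    # cost_ssc, weight of L_mss
    hidden_dims: tuple = (512, 30)
    head_dims: tuple = DEFAULT_HEAD_DIMS
    epochs_pretrain: int = 500
    epochs_joint: int = 300
    refresh_every: int = 50
    lr: float = 1e-3
    wd_coeff: float = 1.0
    norm_p: str = "fro"
    ablation: str = "full"              # "full" | "l1_only"
    sup_reduction: str = "mean"
    c_init: str = "ridge"               # "ridge" | "random"
    c_init_beta: float = 0.5
    seed: int = 0


def _gate_losses_t(Xt, model, snn, ctasnn, wd_coeff, decoder_input=None):
    Z = _encode_t(Xt, model, snn, ctasnn)
    H_in = Z[-1] if decoder_input is None else decoder_input(Z)
    X_hat = _decode_t(H_in, model, snn)
    L_att = (Xt - X_hat).sumsq() * 0.5
    L_1 = L_att
    for k in range(model.n_layers - 1):
        L_1 = L_1 + model.W[k].sumsq() * (0.5 * wd_coeff)
    return Z, X_hat, L_att, L_1


def fit(ds: SpotDataset, snn: NeighborGraph, ctasnn: NeighborGraph | None,
        config: TrainConfig):
    """Run the full schedule; returns (model, embeddings, subspace state,
    head, per-epoch loss reports)."""
    if not ds.normalized:
        raise ValueError("fit expects a normalized, HVG-selected dataset")
    n = ds.n_spots
    if n > sub.MAX_SPOTS:
        raise ValueError(f"n={n} exceeds the O(n^2) memory cap of "
                         f"{sub.MAX_SPOTS} spots")
    rng = np.random.default_rng(config.seed)
    Xt = Tensor(ds.X)
    model = GateModel.create(ds.n_genes, config.hidden_dims,
                             alpha=config.alpha, rng=rng)
    L = model.n_layers
    head = ClassifierHead.create(config.hidden_dims[-1], config.m,
                                 config.head_dims, rng=rng)
    # self-expression parameters, diagonal hard-masked at every pass
    C_raw = [Tensor(rng.uniform(-1e-4, 1e-4, (n, n)), requires_grad=True)
             for _ in range(L)]
    diag_mask = Tensor(1.0 - np.eye(n))
    tau_raw = Tensor(np.full(L, np.log(np.e - 1.0)), requires_grad=True)

    reports: list[LossReport] = []

    def masked_C():
        return [c * diag_mask for c in C_raw]

    def fused(Cm):
        w = tau_raw.softplus()
        num = None
        for k in range(L):
            term = w.take([k]) * Cm[k]
            num = term if num is None else num + term
        return num / w.sum()

    def report(epoch, phase, L_att, L_1, Z_np, y, P_np):
        Cm_np = [(c.data * diag_mask.data) for c in C_raw]
        L_mss = sub.self_expression_loss(Z_np, Cm_np)
        L_reg = sub.coefficient_regularization(Cm_np, config.norm_p)
        L_sup = self_supervised_loss(P_np, y, config.sup_reduction) \
            if y is not None else 0.0
        rep = total_loss({"epoch": epoch, "phase": phase, "L_att": L_att,
                          "L_1": L_1, "L_mss": L_mss, "L_reg": L_reg,
                          "L_sup": L_sup}, config.lam)
        reports.append(rep)
        return rep

    def check_finite(value, epoch, phase):
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite loss at {phase} epoch {epoch}: learning rate "
                "too high or degenerate input")

    # ---- phase 1: pretrain the autoencoder on L_1 only -------------------
    opt = Adam(model.parameters(), lr=config.lr)
    for epoch in range(config.epochs_pretrain):
        Z, _, L_att, L_1 = _gate_losses_t(Xt, model, snn, ctasnn,
                                          config.wd_coeff)
        check_finite(L_1.data, epoch, "pretrain")
        opt.zero_grad()
        L_1.backward()
        opt.step()
        if epoch % 50 == 0 or epoch == config.epochs_pretrain - 1:
            Z_np = [z.data for z in Z]
            P_np = head.forward_t(Z[-1]).data
            report(epoch, "pretrain", float(L_att.data), float(L_1.data),
                   Z_np, None, P_np)

    # ---- phase 2: joint objective with self-supervision ------------------
    if config.ablation == "l1_only":
        for epoch in range(config.epochs_joint):
            Z, _, L_att, L_1 = _gate_losses_t(Xt, model, snn, ctasnn,
                                              config.wd_coeff)
            check_finite(L_1.data, epoch, "joint")
            opt.zero_grad()
            L_1.backward()
            opt.step()
        Z = _encode_t(Xt, model, snn, ctasnn)
        Z_np = [z.data.copy() for z in Z]
        Cm_np = [(c.data * diag_mask.data) for c in C_raw]
        tau = np.log1p(np.exp(tau_raw.data))
        C_F = sub.fuse_coefficients(Cm_np, tau)
        Lam = sub.build_affinity(C_F)
        y = sub.spectral_cluster(Lam, config.m, seed=config.seed)
        P_np = head.forward_t(Z[-1]).data
        report(config.epochs_joint - 1, "joint", float(L_att.data),
               float(L_1.data), Z_np, y, P_np)
    else:
        if config.c_init == "ridge":
            # warm-start each C_k at the closed-form ridge self-expression
            # of the pretrained embeddings, so C_F Z_L is a faithful code
            # from the first joint epoch
            Z0 = _encode_t(Xt, model, snn, ctasnn)
            for k in range(L):
                C_raw[k].data[:] = sub.lsr_self_expression(
                    Z0[k].data, config.c_init_beta)
        params = [*model.parameters(), *C_raw, tau_raw, *head.parameters()]
        opt = Adam(params, lr=config.lr)
        y = None
        for epoch in range(config.epochs_joint):
            if epoch % config.refresh_every == 0:
                Cm_np = [(c.data * diag_mask.data) for c in C_raw]
                tau = np.log1p(np.exp(tau_raw.data))
                Lam = sub.build_affinity(sub.fuse_coefficients(Cm_np, tau))
                y = sub.spectral_cluster(Lam, config.m, seed=config.seed)
            Cm = masked_C()
            C_F_t = fused(Cm)
            Z, _, L_att, L_1 = _gate_losses_t(
                Xt, model, snn, ctasnn, config.wd_coeff,
                decoder_input=lambda Zs: C_F_t @ Zs[-1])
            L_mss = None
            for k in range(L):
                term = (Z[k] - Cm[k] @ Z[k]).sumsq()
                L_mss = term if L_mss is None else L_mss + term
            L_mss = L_mss * (1.0 / (2.0 * L))
            if config.norm_p == "fro":
                L_reg = sum((Cm[k].frob() for k in range(L)),
                            start=Tensor(0.0)) * (1.0 / L)
            else:
                L_reg = sum((Cm[k].abs().sum() for k in range(L)),
                            start=Tensor(0.0)) * (1.0 / L)
            P = head.forward_t(Z[-1])
            picked = P.take_per_row(y).clip(1e-12, 1.0)
            L_sup = -(picked.log().sum())
            if config.sup_reduction == "mean":
                L_sup = L_sup * (1.0 / n)
            total = L_1 + L_reg + L_mss * config.lam + L_sup
            check_finite(total.data, epoch, "joint")
            opt.zero_grad()
            total.backward()
            opt.step()
            reports.append(total_loss(
                {"epoch": epoch, "phase": "joint",
                 "L_att": float(L_att.data), "L_1": float(L_1.data),
                 "L_mss": float(L_mss.data), "L_reg": float(L_reg.data),
                 "L_sup": float(L_sup.data)}, config.lam))
        # final state after the last update
        Z = _encode_t(Xt, model, snn, ctasnn)
        Z_np = [z.data.copy() for z in Z]
        Cm_np = [(c.data * diag_mask.data) for c in C_raw]
        tau = np.log1p(np.exp(tau_raw.data))
        C_F = sub.fuse_coefficients(Cm_np, tau)
        Lam = sub.build_affinity(C_F)
        y = sub.spectral_cluster(Lam, config.m, seed=config.seed)

    X_hat = _decode_t(Tensor(Z_np[-1]) if config.ablation == "l1_only"
                      else Tensor(C_F @ Z_np[-1]), model, snn).data
    emb = EmbeddingSet(Z=Z_np, X_hat=X_hat)
    state = sub.SubspaceState(C=Cm_np, tau=tau, C_F=C_F, Lambda=Lam,
                              Y_clu=y, m=config.m, norm_p=config.norm_p)
    return model, emb, state, head, reports
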