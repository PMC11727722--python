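"""End-to-end orchestration: preprocess -> graphs -> train -> cluster ->
refine -> evaluate -> markers, with every artifact written to an output
directory and fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import clustering, data_io, diffexp, graphs, metrics
from .data_io import SpotDataset
from .training import TrainConfig, fit

logger = logging.getLogger("spotdomains")


@dataclass
class RunConfig:
    """Every knob of a pipeline run; echoed verbatim into the output dir."""

    # graph
    graph: str = "knn"            # "knn" | "radius"
    rad_cutoff: float = 150.0
    knn_k: int = 6
    # attention mix and preclustering
    alpha: float = 0.0
    precluster_resolution: float = 1.0
    # training
    cost_ssc: float = 0.1         # lambda, weight of the self-expression loss
    hidden_dims: tuple = (512, 30)
    epochs_pretrain: int = 500
    epochs_joint: int = 300
    refresh_every: int = 50
    lr: float = 1e-3
    ablation: str = "full"
    # preprocessing
    hvg_n: int = 3000
    target_sum: float = 1e4
    # domain calling
    method: str = "louvain"       # "louvain" | "leiden" | "gmm" | "subspace"
    n_clusters: int = 4           # target_k / mixture components / m
    resolution: float = 1.0       # used when no target tuning
    tune_to_target: bool = True
    refine: bool = True
    r_refine: float = clustering.DEFAULT_R_REFINE
    # misc
    seed: int = 0
    n_top_markers: int = 5

    def validate(self):
        if self.graph not in ("knn", "radius"):
            raise ValueError(f"unknown graph type {self.graph!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
        if self.method not in ("louvain", "leiden", "gmm", "subspace"):
            raise ValueError(f"unknown method {self.method!r}")


def run_pipeline(ds: SpotDataset, config: RunConfig, outdir=None) -> dict:
    """Run the full workflow; returns a result dict and (optionally)
    writes labels/embeddings/losses/metrics/config artifacts."""
    config.validate()
    t0 = time.time()

    # --- preprocessing ----------------------------------------------------
    if not ds.normalized:
        ds = data_io.drop_empty_spots(ds)
        ds = data_io.normalize_log1p(ds, config.target_sum)
    ds = data_io.select_hvg(ds, min(config.hvg_n, ds.n_genes))
    logger.info("preprocessed: %d spots x %d genes", ds.n_spots, ds.n_genes)

    # --- neighbor graphs ----------------------------------------------------
    if config.graph == "radius":
        snn = graphs.build_radius_graph(ds.coords, config.rad_cutoff)
    else:
        snn = graphs.build_knn_graph(ds.coords, config.knn_k)
    pre_labels = graphs.precluster_expression(
        ds, resolution=config.precluster_resolution, seed=config.seed)
    ctasnn = graphs.prune_to_ctasnn(snn, pre_labels)
    logger.info("SNN %d edges, ctaSNN %d edges, %d preclusters",
                snn.adjacency.nnz, ctasnn.adjacency.nnz,
                pre_labels.max() + 1)

    # --- embedding learning -------------------------------------------------
    tcfg = TrainConfig(
        m=config.n_clusters, alpha=config.alpha, lam=config.cost_ssc,
        hidden_dims=tuple(config.hidden_dims),
        epochs_pretrain=config.epochs_pretrain,
        epochs_joint=config.epochs_joint,
        refresh_every=config.refresh_every, lr=config.lr,
        ablation=config.ablation, seed=config.seed)
    model, emb, state, head, reports = fit(ds, snn, ctasnn, tcfg)
    Z = emb.Z[-1]

    # --- domain calling -----------------------------------------------------
    if config.method == "subspace":
        labels = state.Y_clu.copy()
        assign = clustering.DomainAssignment(labels, "subspace",
                                             float(config.n_clusters))
    elif config.method == "gmm":
        assign = clustering.cluster_embeddings(Z, "gmm", config.n_clusters,
                                               seed=config.seed)
    elif config.tune_to_target:
        assign = clustering.tune_resolution(Z, config.method,
                                            config.n_clusters,
                                            seed=config.seed)
        if not assign.exact_k:
            logger.warning("target k=%d not reached; closest k=%d",
                           config.n_clusters, assign.labels.max() + 1)
    else:
        assign = clustering.cluster_embeddings(Z, config.method,
                                               config.resolution,
                                               seed=config.seed)
    labels = assign.labels
    if config.refine:
        labels = clustering.refine_by_neighborhood(labels, ds.coords,
                                                   config.r_refine)
        assign.refined = True
        assign.r_refine = config.r_refine

    # --- evaluation and markers --------------------------------------------
    report = metrics.evaluate(Z, labels, truth=ds.truth_labels)
    markers = diffexp.rank_all_domains(ds, labels)

    result = {
        "dataset": ds, "labels": labels, "assignment": assign,
        "embeddings": Z, "model": model, "subspace": state,
        "loss_reports": reports, "metrics": report, "markers": markers,
        "preclusters": pre_labels,
        "runtime_s": time.time() - t0,
    }
    if outdir is not None:
        _write_artifacts(result, config, Path(outdir))
    return result


def _write_artifacts(result, config: RunConfig, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    ds = result["dataset"]
    pd.DataFrame({"spot_id": ds.spot_ids, "domain": result["labels"]}
                 ).to_csv(outdir / "labels.csv", index=False)
    pd.DataFrame(result["embeddings"], index=ds.spot_ids
                 ).to_csv(outdir / "embeddings.csv")
    pd.DataFrame([dataclasses.asdict(r) for r in result["loss_reports"]]
                 ).to_csv(outdir / "losses.csv", index=False)
    (outdir / "metrics.json").write_text(result["metrics"].to_json())
    cfg = dataclasses.asdict(config)
    cfg["hidden_dims"] = list(cfg["hidden_dims"])
    cfg["head_dims"] = None  # not a RunConfig field; keep echo minimal
    del cfg["head_dims"]
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2))
    mdir = outdir / "markers"
    mdir.mkdir(exist_ok=True)
    for dom, table in result["markers"].items():
        table.head(config.n_top_markers).to_csv(
            mdir / f"domain_{dom}.csv", index=False)


def load_config(path) -> RunConfig:
    """Read a JSON config file (keys = RunConfig fields)."""
    obj = json.loads(Path(path).read_text())
    if "hidden_dims" in obj:
        obj["hidden_dims"] = tuple(obj["hidden_dims"])
    return RunConfig(**obj)
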