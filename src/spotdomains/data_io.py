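"""Reading, writing, and preprocessing of spot-level expression data.

A :class:`SpotDataset` bundles a spots × genes expression matrix with 2-D
spatial coordinates. Preprocessing follows the standard spatial
transcriptomics recipe: drop spots outside the tissue, library-size
normalize + log1p, then keep the most dispersed (highly variable) genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger("spotdomains")

DEFAULT_TARGET_SUM = 1e4
DEFAULT_N_HVG = 3000


@dataclass
class SpotDataset:
    """Spots × genes expression with planar coordinates.

    Invariants: row counts of ``X``, ``coords``, ``spot_ids`` agree;
    ``gene_ids`` matches columns of ``X``; ids are unique; entries finite.
    """

    X: np.ndarray
    coords: np.ndarray
    spot_ids: list[str]
    gene_ids: list[str]
    truth_labels: np.ndarray | None = None
    normalized: bool = False
    hvg_mask: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n, g = self.X.shape
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 2)")
        if len(self.spot_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("expression matrix contains non-finite entries")
        if not self.normalized and np.any(self.X < 0):
            raise ValueError("raw counts must be non-negative")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels, dtype=int)
            if self.truth_labels.shape != (n,):
                raise ValueError("truth_labels length mismatch")

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


def load_spot_dataset(matrix_path, coords_path, dialect="dense",
                      spots_axis="rows") -> SpotDataset:
    """Load a dataset from a matrix file plus a coordinate table.

    ``dialect`` is ``"dense"`` (CSV/TSV, header row = gene ids, first column
    = spot ids) or ``"mtx"`` (MatrixMarket triplets; duplicate entries sum,
    spot/gene ids are read from sibling ``*_spots.txt`` / ``*_genes.txt``
    files or synthesized). The coordinate table needs columns
    ``spot_id, x, y``. Spots missing from either side are dropped with a
    logged count.
    """
    if dialect == "dense":
        sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        X = df.to_numpy(dtype=np.float64)
        spot_ids = [str(s) for s in df.index]
        gene_ids = [str(g) for g in df.columns]
    elif dialect == "mtx":
        M = mmread(str(matrix_path))  # duplicates are summed by convention
        X = np.asarray(M.todense() if hasattr(M, "todense") else M,
                       dtype=np.float64)
        if spots_axis == "cols":
            X = X.T
        spot_ids = _sidecar_ids(matrix_path, "spots", X.shape[0], "spot")
        gene_ids = _sidecar_ids(matrix_path, "genes", X.shape[1], "gene")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if len(set(spot_ids)) != len(spot_ids):
        dup = next(s for s in spot_ids if spot_ids.count(s) > 1)
        raise ValueError(f"duplicate spot id in matrix: {dup!r}")

    csep = "\t" if str(coords_path).endswith((".tsv", ".txt")) else ","
    cdf = pd.read_csv(coords_path, sep=csep)
    cdf.columns = [c.strip().lower() for c in cdf.columns]
    for col in ("spot_id", "x", "y"):
        if col not in cdf.columns:
            raise ValueError(f"coordinate table missing column {col!r}")
    cdf["spot_id"] = cdf["spot_id"].astype(str)
    if cdf["spot_id"].duplicated().any():
        dup = cdf.loc[cdf["spot_id"].duplicated(), "spot_id"].iloc[0]
        raise ValueError(f"duplicate spot id in coordinates: {dup!r}")
    for col in ("x", "y"):
        vals = pd.to_numeric(cdf[col], errors="coerce")
        if vals.isna().any():
            bad = cdf.loc[vals.isna(), "spot_id"].iloc[0]
            raise ValueError(f"non-numeric {col} coordinate for spot {bad!r}")
        cdf[col] = vals

    cmap = {s: (x, y) for s, x, y in zip(cdf["spot_id"], cdf["x"], cdf["y"])}
    keep = [i for i, s in enumerate(spot_ids) if s in cmap]
    dropped = len(spot_ids) - len(keep)
    if dropped:
        logger.warning("dropping %d spot(s) without coordinates", dropped)
    if not keep:
        raise ValueError("no spots shared between matrix and coordinates")
    spot_ids = [spot_ids[i] for i in keep]
    coords = np.array([cmap[s] for s in spot_ids], dtype=np.float64)
    return SpotDataset(X[keep], coords, spot_ids, gene_ids)


def _sidecar_ids(matrix_path, kind, n, prefix):
    from pathlib import Path

    p = Path(str(matrix_path))
    side = p.with_name(p.stem + f"_{kind}.txt")
    if side.exists():
        ids = side.read_text().split()
        if len(ids) != n:
            raise ValueError(f"{side} lists {len(ids)} ids, expected {n}")
        return ids
    return [f"{prefix}{i}" for i in range(n)]


def filter_spots(ds: SpotDataset, mask) -> SpotDataset:
    """Subset spots by a boolean mask (e.g. in-tissue), order preserved."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ds.n_spots,):
        raise ValueError("mask length does not match spot count")
    if not mask.any():
        raise ValueError("no spots remain after filtering")
    return replace(
        ds,
        X=ds.X[mask],
        coords=ds.coords[mask],
        spot_ids=[s for s, m in zip(ds.spot_ids, mask) if m],
        truth_labels=None if ds.truth_labels is None else ds.truth_labels[mask],
    )


def drop_empty_spots(ds: SpotDataset) -> SpotDataset:
    """Remove zero-library-size spots (logged) so normalization is defined."""
    sums = ds.X.sum(axis=1)
    mask = sums > 0
    if not mask.all():
        logger.warning("removing %d spot(s) with zero counts",
                       int((~mask).sum()))
    return filter_spots(ds, mask)


def normalize_log1p(ds: SpotDataset, target_sum: float = DEFAULT_TARGET_SUM
                    ) -> SpotDataset:
    """Scale each spot to ``target_sum`` total counts, then log(1 + x)."""
    if ds.normalized:
        raise ValueError("dataset is already normalized")
    sums = ds.X.sum(axis=1)
    if np.any(sums <= 0):
        bad = [ds.spot_ids[i] for i in np.flatnonzero(sums <= 0)]
        raise ValueError(f"zero library size for spots: {bad}")
    X = np.log1p(ds.X * (target_sum / sums[:, None]))
    return replace(ds, X=X, normalized=True)


def select_hvg(ds: SpotDataset, n_top: int = DEFAULT_N_HVG) -> SpotDataset:
    """Keep the ``n_top`` genes with the largest dispersion.

    Dispersion is variance/mean of the normalized matrix; zero-mean genes
    get dispersion 0. Ties break by gene id; gene order is preserved.
    """
    if not ds.normalized:
        raise ValueError("select_hvg expects a normalized dataset")
    if not 1 <= n_top <= ds.n_genes:
        raise ValueError(f"n_top={n_top} outside [1, {ds.n_genes}]")
    mean = ds.X.mean(axis=0)
    var = ds.X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = sorted(range(ds.n_genes), key=lambda j: (-disp[j], ds.gene_ids[j]))
    keep = np.zeros(ds.n_genes, dtype=bool)
    keep[order[:n_top]] = True
    return replace(
        ds,
        X=ds.X[:, keep],
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
        hvg_mask=keep,
    )


# ---- fixture / artifact round-trip formats -------------------------------

def write_dense(ds: SpotDataset, path) -> None:
    """Dense CSV: first column spot ids, header row gene ids."""
    pd.DataFrame(ds.X, index=ds.spot_ids, columns=ds.gene_ids).to_csv(path)


def save_archive(ds: SpotDataset, path) -> None:
    """Single-file JSON archive of the full dataset (small fixtures only)."""
    obj = {
        "X": ds.X.tolist(),
        "coords": ds.coords.tolist(),
        "spot_ids": ds.spot_ids,
        "gene_ids": ds.gene_ids,
        "truth_labels": None if ds.truth_labels is None
        else ds.truth_labels.tolist(),
        "normalized": ds.normalized,
        "hvg_mask": None if ds.hvg_mask is None else ds.hvg_mask.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_archive(path) -> SpotDataset:
    with open(path) as fh:
        obj = json.load(fh)
    return SpotDataset(
        X=np.array(obj["X"], dtype=np.float64),
        coords=np.array(obj["coords"], dtype=np.float64),
        spot_ids=list(obj["spot_ids"]),
        gene_ids=list(obj["gene_ids"]),
        truth_labels=None if obj["truth_labels"] is None
        else np.array(obj["truth_labels"], dtype=int),
        normalized=bool(obj["normalized"]),
        hvg_mask=None if obj.get("hvg_mask") is None
        else np.array(obj["hvg_mask"], dtype=bool),
    )
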