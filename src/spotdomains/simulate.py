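"""Synthetic spatial transcriptomics and union-of-subspaces generators.

``generate_layered_tissue`` emulates a layered cortical section: spots on a
hex (or square) lattice partitioned into spatially contiguous domains
(horizontal bands or Voronoi cells), with domain-specific marker genes
whose Poisson rate is shifted upward inside their domain. The lattice
spacing is normalized to 1.0 so radius parameters are in inter-spot units.

``generate_subspace_points`` draws points from a union of random linear
subspaces — the premise of the self-expression model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import SpotDataset


@dataclass
class SyntheticSpec:
    """Study conditions for the layered-tissue generator."""

    rows: int = 30
    cols: int = 30
    k_domains: int = 4
    geometry: str = "bands"          # "bands" | "voronoi"
    lattice: str = "hex"             # "hex" | "square"
    n_genes: int = 100
    markers_per_domain: int = 10
    marker_effect: float = 5.0       # Poisson-rate shift inside the domain
    baseline_mean: float = 1.0
    noise: str = "poisson"           # "poisson" | "gaussian"
    gaussian_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.k_domains < 2:
            raise ValueError("need at least 2 domains")
        if self.markers_per_domain * self.k_domains > self.n_genes:
            raise ValueError("more markers than genes")
        if self.geometry not in ("bands", "voronoi"):
            raise ValueError(f"unknown geometry: {self.geometry!r}")
        if self.noise not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise model: {self.noise!r}")


def _lattice_coords(spec: SyntheticSpec) -> np.ndarray:
    r = np.repeat(np.arange(spec.rows), spec.cols)
    c = np.tile(np.arange(spec.cols), spec.rows)
    if spec.lattice == "hex":
        x = c + 0.5 * (r % 2)
        y = r * (np.sqrt(3.0) / 2.0)
    else:
        x = c.astype(float)
        y = r.astype(float)
    return np.column_stack([x, y]).astype(np.float64)


def generate_layered_tissue(spec: SyntheticSpec
                            ) -> tuple[SpotDataset, dict[int, list[str]]]:
    """Returns (dataset with truth_labels, marker map domain -> gene ids)."""
    rng = np.random.default_rng(spec.seed)
    coords = _lattice_coords(spec)
    n = coords.shape[0]
    if spec.geometry == "bands":
        # equal-size contiguous bands along the row-major sweep (exactly
        # n/k spots each when k divides n; boundary may split a row)
        truth = ((np.arange(n) * spec.k_domains) // n).astype(int)
    else:
        seeds = coords[rng.choice(n, size=spec.k_domains, replace=False)]
        d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2)
        truth = d.argmin(axis=1).astype(int)

    gene_ids = [f"g{j:04d}" for j in range(spec.n_genes)]
    marker_map: dict[int, list[str]] = {}
    rates = np.full((n, spec.n_genes), spec.baseline_mean, dtype=np.float64)
    for dom in range(spec.k_domains):
        lo = dom * spec.markers_per_domain
        hi = lo + spec.markers_per_domain
        marker_map[dom] = gene_ids[lo:hi]
        rates[truth == dom, lo:hi] += spec.marker_effect

    if spec.noise == "poisson":
        X = rng.poisson(rates).astype(np.float64)
    else:
        X = np.maximum(rates + rng.normal(0.0, spec.gaussian_sigma,
                                          rates.shape), 0.0)
    spot_ids = [f"s{i:04d}" for i in range(n)]
    ds = SpotDataset(X=X, coords=coords, spot_ids=spot_ids,
                     gene_ids=gene_ids, truth_labels=truth)
    return ds, marker_map


def generate_subspace_points(k: int, sub_dim: int, ambient_dim: int,
                             n_per: int, noise_sigma: float = 0.0,
                             seed: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Points from k random ``sub_dim``-dimensional linear subspaces of
    R^ambient_dim, plus isotropic Gaussian noise; returns (X, truth)."""
    if sub_dim >= ambient_dim:
        raise ValueError("sub_dim must be below ambient_dim")
    rng = np.random.default_rng(seed)
    blocks, truth = [], []
    for s in range(k):
        basis, _ = np.linalg.qr(rng.normal(size=(ambient_dim, sub_dim)))
        coeffs = rng.normal(size=(n_per, sub_dim))
        pts = coeffs @ basis.T
        if noise_sigma > 0:
            pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
        blocks.append(pts)
        truth.append(np.full(n_per, s))
    return np.vstack(blocks), np.concatenate(truth).astype(int)


def corrupt_labels(labels, frac: float, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Reassign exactly round(frac * n) spots to a different random label.

    Returns (corrupted labels, indices of the corrupted spots).
    """
    labels = np.asarray(labels, dtype=int)
    if not 0.0 <= frac < 1.0:
        raise ValueError("frac must be in [0, 1)")
    uniq = np.unique(labels)
    n_flip = int(round(frac * len(labels)))
    if n_flip == 0:
        return labels.copy(), np.array([], dtype=int)
    if len(uniq) < 2:
        raise ValueError("cannot corrupt a single-label assignment")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(labels), size=n_flip, replace=False)
    out = labels.copy()
    for i in idx:
        others = uniq[uniq != labels[i]]
        out[i] = rng.choice(others)
    return out, np.sort(idx)
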