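# Methods

## Model

`spotdomains` treats spatial-domain identification as representation
learning on a spot graph followed by clustering. The assumptions are:

- **Local coherence.** A spot's expression is informative about its
  spatial neighbors', so neighbor aggregation denoises the profile. The
  neighborhood is a radius graph (strict `< r`) or a union-symmetrized
  k-NN graph (k = 6, matching the hexagonal Visium lattice), always with
  self-loops so a spot is its own neighbor.
- **Cell-type boundaries.** Aggregation should not mix across tissue
  boundaries. Expression-only Louvain preclusters (PCA to 30 components,
  15-NN graph, resolution 1.0) prune the graph into the cell-type-aware
  variant; the attention mix α ∈ [0, 1] interpolates between the plain
  spatial graph (α = 0) and the pruned one (α = 1). The preclustering
  pipeline is a package choice — only "Louvain on expression" is inherent
  to the method; all pieces are configurable.
- **Union of subspaces.** Embeddings of spots from the same domain lie
  near a common low-dimensional linear subspace, so each spot's embedding
  is approximately a linear combination of its domain-mates
  (Z ≈ C Z, diag(C) = 0). Per-layer coefficient matrices C_k are fused by
  trainable positive weights τ_k (softplus-reparameterized, initialized at
  1) into C_F, and Λ = ½(|C_F| + |C_Fᵀ|) feeds normalized spectral
  clustering (symmetric Laplacian, m smallest eigenvectors, row
  normalization, k-means with 10 restarts).

The autoencoder ties decoder weights to encoder transposes and reuses the
encoder's attention values, so the decoder owns no parameters; attention
logits pass through a sigmoid (not the LeakyReLU of generic graph
attention) before the per-neighborhood softmax, and the blended attention
is used as-is without renormalization (each component is already
row-stochastic; the blend of two distributions is one too when the graphs
coincide, and deliberately sub-stochastic on pruned rows otherwise).

## Objective and schedule

- Phase 1 (default 500 epochs): minimize
  `L_1 = ½‖X − X̂‖²_F + wd·½‖W_1‖²_F` with the decoder fed Z_L directly.
- Phase 2 (default 300 epochs): decoder fed C_F·Z_L; minimize
  `L_total = L_1 + L_reg + λ·L_mss + L_sup` where
  `L_mss = 1/(2L)·Σ_k ‖Z_k − C_k Z_k‖²_F`,
  `L_reg = 1/L·Σ_k ‖C_k‖_F` (plain Frobenius by default; the norm is
  selectable because the regularizer's norm is an open choice — L1 gives
  sparser coefficients), and `L_sup` is the mean cross-entropy between the
  classifier head's probabilities and the current spectral labels Y_clu,
  refreshed every 50 epochs. λ (exposed as `cost_ssc`) defaults to 0.1.
- The printed form of the self-supervision term (probabilities inside the
  log's argument swapped with the labels) is degenerate for hard labels;
  the standard cross-entropy with the clustering label as target is used,
  averaged over spots for scale stability (a plain-sum switch exists).
- The classifier head is the dimension chain d_L × 128 × 64 × 32 × m:
  four linear maps with ReLU between and a row softmax at the end.

**Self-expression warm start.** Naively switching the decoder's input from
Z_L to C_F·Z_L with C at a near-zero random initialization collapses the
reconstruction and measurably degrades the embedding for hundreds of
epochs. At the phase boundary each C_k is therefore initialized at the
closed-form minimizer of ½‖Z_k − C Z_k‖²_F + β‖C‖²_F subject to
diag(C) = 0 (β = 0.5), computed with one O(n³) inverse via the
least-squares-regression identity C_ij = −D_ji/D_ii,
D = (Z Zᵀ + 2βI)⁻¹. `c_init="random"` restores the naive start.

**Optimizer.** Adam at lr 1e-3 throughout (lr 1e-4 needs several times
more epochs to move Glorot-initialized weights appreciably, which the
default budgets do not provide). Training is full-batch on the whole
graph; float64; a NaN in any loss aborts with a diagnostic. The O(L·n²)
self-expression parameters cap the method at 20,000 spots.

## Parameters that matter

| knob | default | meaning |
|---|---|---|
| `rad_cutoff` / `knn_k` | 150 (coordinate units) / 6 | neighbor graph scale; 6-NN suits hex lattices |
| `alpha` | 0 | ctaSNN attention weight (0.5–0.7 for heterogeneous tissue) |
| `cost_ssc` (λ) | 0.1 | weight of the self-expression loss (1.0 in the tumor-like preset) |
| hidden dims | (512, 30) | encoder widths; Z_L is the 30-d embedding used downstream |
| `n_clusters` | — | target domain count m (resolution is bisected to reach it) |
| `r_refine` | 50 | majority-vote radius, in the coordinates' native units; for the unit-spaced synthetic lattice use ≈1.5 |
| `hvg_n` | 3000 | highly variable genes kept (dispersion = variance/mean of the log-normalized matrix) |

## Domain calling and refinement

Louvain (igraph multilevel) and Leiden (RBConfiguration) run on an
unweighted 15-NN graph of Z_L; `tune_resolution` bisects [0.05, 5.0] in at
most 60 evaluations and falls back to the closest achieved count with a
flag. The Gaussian-mixture route (full covariance, k-means init, 10
restarts) is the model-based alternative for single-cell-resolution data.
Refinement is a single simultaneous pass: each spot takes the modal label
of its neighbors within `r_refine`, computed entirely from the
pre-refinement labels (simultaneous rather than sequential updates keep
the operation order-independent and deterministic); ties keep the spot's
own label, otherwise the lowest label id wins; isolated spots are
untouched. Refinement can therefore never invent a label.

The spectral labels Y_clu are primarily a self-supervision signal: on
synthetic tissue they score well below the Louvain/GMM re-clustering of
the embeddings, so the pipeline's `method="subspace"` route exists for
completeness but is not the recommended final caller.

## Validity metrics

ARI uses the contingency-table form of the chance-corrected Rand index.
Davies–Bouldin and Calinski–Harabasz follow their standard definitions
(mean distance to centroid / centroid gaps; between- over within-cluster
scatter). S_Dbw is the 2001 Halkidi–Vazirgiannis variant:
`Scat = mean_i ‖σ(c_i)‖ / ‖σ(D)‖` on per-dimension variance vectors, and
`Dens_bw` compares point density at cluster-pair midpoints to the denser
of the two centroids within radius `stdev = √(Σ‖σ(c_i)‖)/k`; a zero
denominator contributes zero. Degenerate geometries raise: coincident
centroids (DB), zero within-cluster scatter (CH), zero global variance
(S_Dbw). Tests pin all four to independently coded oracles. Metrics are
computed on the embedding matrix by default, not on raw expression.

## Marker genes

Welch's unequal-variance t-test per gene, one domain against all other
spots, on log-normalized values; genes with zero variance in both groups
get t = 0, p = 1; Benjamini–Hochberg across genes within each domain
(the correction is this package's addition); ranking by |t| with gene-id
tie-breaks.

## Synthetic data: what it does and does not cover

`generate_layered_tissue` emulates a layered section: a hex (or square)
lattice with unit spacing, k spatially contiguous domains (equal-size
row-major bands, or Voronoi cells), Poisson counts at `baseline_mean = 1`
with each domain's `markers_per_domain = 10` marker genes shifted by
`marker_effect = 5` inside the domain (a strong, cleanly separable
signal: a GMM on 10 principal components already reaches ARI ≥ 0.8, which
the tests assert as a calibration guard). Defaults: 30×30 spots, 4
domains, 100 genes. `generate_subspace_points` draws from k random
orthonormal subspaces plus Gaussian noise. Not modeled: dropout/zero
inflation, library-size variation across spots, histology, batch effects,
doublets, irregular spot spacing. Passing tests therefore demonstrate the
machinery is correct and recovers planted structure — not that real-tissue
accuracy matches any published benchmark.

## Problem sizes used by the tests and the acceptance script

End-to-end recovery runs the full default schedule (500 + 300 epochs) on
the 30×30 / 4-band / 5×-effect tissue with 100 genes and hidden dims
(512, 30). The ablation ensemble uses 20 replicates of a 12×12 lattice
(60 genes, 8 markers/domain, hidden (32, 12), 200 + 300 epochs) — sizes
chosen so a replicate trains in a few seconds while the two objectives
remain distinguishable. The ridge closed-form check trains a single frozen
layer (n = 15, d = 4) for 20,000 epochs at lr 1e-2 to reach the 1e-3
agreement band; the union-of-subspaces fixture is 2 planes in 6-d ambient
space, 20 points each, noiseless.

## Numerical choices and edge cases

- Strict `<` in the radius rule; k-NN distance ties break to the lower
  spot index; k-NN symmetrization is by union (no spot loses neighbors).
- Spots with zero counts are removed (logged) before normalization;
  normalizing twice raises; HVG selection requires normalized input.
- The decoder's output layer uses identity activation so reconstructions
  can take any log-normalized value (the hidden activations are ELU).
- Softmax stability: attention logits are sigmoid outputs in (0, 1), so
  the segment softmax needs no max-shift; the classifier head subtracts
  the row max. Cross-entropy probabilities are clipped to [1e-12, 1].
- Spectral clustering regularizes zero degrees at 1e-12 and symmetrizes
  the Laplacian before `eigh`; k-means uses 10 restarts with a fixed seed.
- All randomness flows from a single integer seed (numpy Generator,
  igraph RNG seeded per call, leidenalg/sklearn seeds), so identical
  configurations reproduce outputs bitwise on the same platform.

## Known limitations

- O(n²) memory/compute in the self-expression module (hard 20,000-spot
  cap); no sparse or landmark approximation, no out-of-sample extension.
- Whole-graph training only — no mini-batching, no GPU path.
- No histology, multi-sample integration, trajectory inference, or UMAP;
  the library stops at embeddings, labels, metrics, and marker tables.
- mclust-style model selection is approximated by a full-covariance GMM
  without the EEE/VVV BIC sweep.
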