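"""Marker-gene ranking per spatial domain.

Welch's (unequal-variance) t-test per gene, domain vs all other spots, on
the normalized expression, with Benjamini-Hochberg correction across genes
within each domain and ranking by |t| descending (ties by gene id).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import SpotDataset


def rank_genes_ttest(ds: SpotDataset, labels, domain: int) -> pd.DataFrame:
    """Marker table for one domain: columns gene, t, pval, padj, lfc, rank.

    Genes with zero variance in both groups get t = 0, p = 1 (no evidence
    either way). log-fold-change is the difference of group means (the
    expression is already log-scale).
    """
    labels = np.asarray(labels)
    if labels.shape != (ds.n_spots,):
        raise ValueError("label length mismatch")
    in_dom = labels == domain
    if not in_dom.any():
        raise ValueError(f"domain {domain} not present")
    if in_dom.sum() < 2 or (~in_dom).sum() < 2:
        raise ValueError("both groups need at least 2 spots")
    A, B = ds.X[in_dom], ds.X[~in_dom]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    flat = ~np.isfinite(t)  # zero variance in both groups
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    lfc = A.mean(axis=0) - B.mean(axis=0)
    df = pd.DataFrame({
        "gene": ds.gene_ids, "t": t, "pval": p, "padj": padj, "lfc": lfc,
    })
    df = df.sort_values(["t", "gene"], key=lambda c: -c.abs()
                        if c.name == "t" else c).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rank_all_domains(ds: SpotDataset, labels) -> dict[int, pd.DataFrame]:
    """Marker tables for every domain with at least 2 spots."""
    labels = np.asarray(labels)
    out = {}
    for dom in np.unique(labels):
        if (labels == dom).sum() >= 2 and (labels != dom).sum() >= 2:
            out[int(dom)] = rank_genes_ttest(ds, labels, int(dom))
    return out
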