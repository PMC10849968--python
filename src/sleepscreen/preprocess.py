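"""Cell QC, normalization and per-cluster aggregation.

QC removes cells with fewer than 200 detected genes, cells whose
mitochondrial UMI fraction exceeds a per-run threshold, and cells belonging
to excluded conditions (by default the ZT2 wake condition, which the study
design lacks a counterpart for).  Kept cells are normalized to 10,000 counts
and log1p-transformed; a parallel counts-per-million (CPM) layer feeds the
expression filters of the cycling screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
import scipy.stats as st

__all__ = [
    "QcParams",
    "qc_filter",
    "normalize",
    "exclude_run_effect_genes",
    "cluster_condition_means",
]


@dataclass
class QcParams:
    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.30
    per_run_mito_fraction: dict[str, float] = field(default_factory=dict)
    excluded_conditions: frozenset[str] = frozenset({"ZT2-Wake"})
    mito_gene_prefix: str = "mt:"

    def __post_init__(self) -> None:
        for f in [self.max_mito_fraction, *self.per_run_mito_fraction.values()]:
            if not 0 < f <= 1:
                raise ValueError(f"mito fraction threshold {f} outside (0, 1]")

    def mito_threshold(self, run: str) -> float:
        return self.per_run_mito_fraction.get(run, self.max_mito_fraction)


def qc_filter(adata: ad.AnnData, params: QcParams | None = None) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells; returns the kept subset and a per-cell QC report.

    The report has one row per input cell with columns ``kept`` and
    ``reason`` (the first failed check among ``excluded_condition``,
    ``min_genes``, ``mito_fraction``; empty if kept).
    """
    params = params or QcParams()
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(params.mito_gene_prefix)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 1.0)
    runs = adata.obs["run"].astype(str) if "run" in adata.obs else pd.Series("", index=adata.obs_names)
    thresholds = runs.map(params.mito_threshold).to_numpy()

    reason = np.full(adata.n_obs, "", dtype=object)
    excluded = adata.obs["condition"].astype(str).isin(params.excluded_conditions).to_numpy()
    reason[excluded] = "excluded_condition"
    low = (n_genes < params.min_genes_per_cell) & (reason == "")
    reason[low] = "min_genes"
    hi_mito = (mito_frac > thresholds) & (reason == "")
    reason[hi_mito] = "mito_fraction"

    report = pd.DataFrame(
        {"cell_id": adata.obs_names, "kept": reason == "", "reason": reason}
    )
    kept = adata[reason == ""].copy()
    if kept.n_obs == 0:
        raise ValueError("QC removed every cell")
    return kept, report


def normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalize to ``target_sum`` per cell, then log1p.

    The returned AnnData keeps raw counts in ``.layers['counts']`` and a CPM
    view in ``.layers['cpm']``; ``.X`` holds the log-normalized values.
    Cells with zero total counts are rejected by name.
    """
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; run QC first")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    cpm = X.astype(float).multiply(1e6 / totals[:, None]).tocsr()
    out.layers["cpm"] = cpm
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def exclude_run_effect_genes(
    adata: ad.AnnData,
    alpha: float = 0.001,
    exclude_list: set[str] | None = None,
) -> pd.Series:
    """Boolean mask (indexed by gene) of genes with run-associated expression.

    A gene is masked if it is on the explicit ``exclude_list``, or if a
    Kruskal–Wallis test of its normalized expression across runs — run within
    each cluster and pooled over clusters by Fisher's method — is significant
    after Bonferroni correction at ``alpha``.  With fewer than two runs only
    the explicit list applies.  Masked genes should be skipped by all screens.
    """
    exclude_list = exclude_list or set()
    mask = pd.Series(False, index=adata.var_names, name="run_effect")
    mask[mask.index.isin(exclude_list)] = True

    runs = adata.obs["run"].astype(str) if "run" in adata.obs else None
    if runs is None or runs.nunique() < 2:
        return mask

    X = adata.X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X)
    chi2 = np.zeros(adata.n_vars)
    dof = np.zeros(adata.n_vars, dtype=int)
    for cl in adata.obs["cluster"].astype(str).unique():
        sel = (adata.obs["cluster"].astype(str) == cl).to_numpy()
        run_labels = runs[sel]
        groups_idx = [np.flatnonzero((run_labels == r).to_numpy()) for r in run_labels.unique()]
        groups_idx = [g for g in groups_idx if len(g) >= 2]
        if len(groups_idx) < 2:
            continue
        sub = dense[sel]
        for g in range(adata.n_vars):
            samples = [sub[idx, g] for idx in groups_idx]
            flat = np.concatenate(samples)
            if np.all(flat == flat[0]):
                continue  # constant gene: no evidence
            try:
                stat, p = st.kruskal(*samples)
            except ValueError:
                continue
            if np.isfinite(p):
                p = max(p, 1e-300)
                chi2[g] += -2.0 * np.log(p)
                dof[g] += 2
    tested = dof > 0
    p_fisher = np.ones(adata.n_vars)
    p_fisher[tested] = st.chi2.sf(chi2[tested], dof[tested])
    bonf = np.minimum(p_fisher * tested.sum(), 1.0) if tested.any() else p_fisher
    mask[(bonf < alpha) & tested] = True
    return mask


def cluster_condition_means(
    adata: ad.AnnData,
    cluster: str,
    layer: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean expression per (gene, condition) within one cluster.

    Returns a genes x conditions DataFrame and a per-condition cell-count
    Series.  Conditions with zero cells are absent from the table (missing,
    never imputed as zero).
    """
    in_cluster = adata.obs["cluster"].astype(str) == str(cluster)
    if not in_cluster.any():
        raise KeyError(f"unknown cluster {cluster!r}")
    sub = adata[in_cluster.to_numpy()]
    X = sub.layers[layer] if layer else sub.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    conds = sub.obs["condition"].astype(str)
    means = {}
    counts = {}
    for cond in conds.unique():
        rows = (conds == cond).to_numpy()
        counts[cond] = int(rows.sum())
        means[cond] = np.asarray(X[rows].mean(axis=0)).ravel()
    table = pd.DataFrame(means, index=adata.var_names)
    return table, pd.Series(counts, name="n_cells")
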