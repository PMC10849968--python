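"""Sleep-vs-wake differential expression and neurotransmitter assignment.

Per cluster, every gene is compared between the pooled sleep and pooled wake
cell groups with a two-tailed Wilcoxon rank-sum test (exact null when both
groups have at most 20 cells and the pooled sample is tie-free; otherwise
the tie-corrected normal approximation), BH-corrected across the cluster's
genes.  The fold change is ``log2`` of the ratio of de-logged group means
with a small pseudocount.  A gene is a DEG when the corrected p is below
alpha and |logFC| exceeds the cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegParams",
    "rank_sum_test",
    "group_log2_fc",
    "SleepWakeDEA",
    "DegResults",
    "assign_neurotransmitter",
]

EXACT_MAX_N = 20


@dataclass
class DegParams:
    alpha: float = 0.05
    logfc_cut: float = 0.5
    pseudocount: float = 1e-9
    min_cells_per_group: int = 3

    def __post_init__(self) -> None:
        if self.logfc_cut < 0:
            raise ValueError("logfc_cut must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed Wilcoxon rank-sum p-value for one gene.

    Exact enumeration of the Mann–Whitney null when both samples have at
    most ``EXACT_MAX_N`` observations and the pooled sample has no ties;
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(x.size, y.size) <= EXACT_MAX_N) else "asymptotic"
    return float(st.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def group_log2_fc(
    x_log: np.ndarray, y_log: np.ndarray, pseudocount: float = 1e-9
) -> np.ndarray:
    """log2 fold change of de-logged group means (x over y), per gene.

    Inputs are log1p-normalized expression matrices (cells x genes); means
    are taken on the de-logged (``expm1``) scale.
    """
    mx = np.expm1(np.asarray(x_log)).mean(axis=0)
    my = np.expm1(np.asarray(y_log)).mean(axis=0)
    return np.log2((mx + pseudocount) / (my + pseudocount))


class DegResults:
    """Per-(cluster, gene) differential-expression table."""

    def __init__(self, table: pd.DataFrame, skipped: dict[str, str], params: DegParams):
        self.table = table
        self.skipped = skipped
        self.params = params

    @property
    def n_deg(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=int)
        return self.table.groupby("cluster", observed=True)["is_deg"].sum().astype(int)

    def significant(self, cluster: str) -> set[str]:
        """Genes with BH-corrected p below alpha (no fold-change cut)."""
        t = self.table
        sel = (t["cluster"] == cluster) & (t["p_bh"] < self.params.alpha)
        return set(t.loc[sel, "gene"])

    def degs(self, cluster: str) -> set[str]:
        t = self.table
        return set(t.loc[(t["cluster"] == cluster) & t["is_deg"], "gene"])

    def summary(self) -> pd.DataFrame:
        out = self.table.groupby("cluster", observed=True).agg(
            n_tested=("gene", "size"), n_deg=("is_deg", "sum")
        )
        return out.reset_index()

    def to_tsv(self, path) -> None:
        t = self.table.copy()
        t["neg_log10_p_bh"] = -np.log10(np.maximum(t["p_bh"], 1e-300))
        t.to_csv(path, sep="\t", index=False)


class SleepWakeDEA:
    """Sleep-vs-wake differential expression across clusters.

    Parameters
    ----------
    adata : AnnData
        Log-normalized dataset with ``cluster`` and ``condition`` in ``.obs``.
    design : ConditionDesign
        Supplies the pooled sleep and wake condition groups.
    """

    def __init__(self, adata: ad.AnnData, design, params: DegParams | None = None,
                 clusters=None, gene_mask=None):
        self.adata = adata
        self.design = design
        self.params = params or DegParams()
        self.clusters = [str(c) for c in (
            clusters if clusters is not None else adata.obs["cluster"].astype(str).unique()
        )]
        self.gene_mask = gene_mask

    def fit(self) -> DegResults:
        p = self.params
        conds = self.adata.obs["condition"].astype(str)
        in_sleep = conds.isin(self.design.sleep_conditions).to_numpy()
        in_wake = conds.isin(self.design.wake_conditions).to_numpy()
        genes = self.adata.var_names.to_numpy()
        keep = np.ones(len(genes), dtype=bool)
        if self.gene_mask is not None:
            keep &= ~self.gene_mask.reindex(self.adata.var_names, fill_value=False).to_numpy()

        X = self.adata.X
        if sp.issparse(X):
            X = X.toarray()
        X = np.asarray(X)

        tables = []
        skipped: dict[str, str] = {}
        for cl in self.clusters:
            in_cl = (self.adata.obs["cluster"].astype(str) == cl).to_numpy()
            xs = X[in_cl & in_sleep][:, keep]
            xw = X[in_cl & in_wake][:, keep]
            if min(xs.shape[0], xw.shape[0]) < p.min_cells_per_group:
                skipped[cl] = (
                    f"{xs.shape[0]} sleep / {xw.shape[0]} wake cells, "
                    f"need >= {p.min_cells_per_group} each"
                )
                continue
            if max(xs.shape[0], xw.shape[0]) <= EXACT_MAX_N:
                pvals = np.array([
                    rank_sum_test(xs[:, g], xw[:, g]) for g in range(xs.shape[1])
                ])
            else:
                pvals = st.mannwhitneyu(
                    xs, xw, alternative="two-sided", method="asymptotic", axis=0
                ).pvalue
                pooled = np.vstack([xs, xw])
                constant = pooled.max(axis=0) == pooled.min(axis=0)
                pvals = np.where(constant | ~np.isfinite(pvals), 1.0, pvals)
            logfc = group_log2_fc(xs, xw, p.pseudocount)
            p_bh = multipletests(pvals, method="fdr_bh")[1]
            tables.append(pd.DataFrame({
                "cluster": cl,
                "gene": genes[keep],
                "logfc": logfc,
                "p": pvals,
                "p_bh": p_bh,
                "is_deg": (p_bh < p.alpha) & (np.abs(logfc) > p.logfc_cut),
            }))
        table = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["cluster", "gene", "logfc", "p", "p_bh", "is_deg"])
        )
        return DegResults(table, skipped, p)


NT_THRESHOLDS = {"VAChT": 0.5, "Gad1": 0.4, "VGlut": 0.5}
NT_CLASSES = {"VAChT": "cholinergic", "Gad1": "GABAergic", "VGlut": "glutamatergic"}


def assign_neurotransmitter(
    adata: ad.AnnData, thresholds: dict[str, float] | None = None
) -> pd.Series:
    """Classify cells by fast-neurotransmitter marker expression.

    A cell whose normalized expression of exactly one of *VAChT* (vesicular
    acetylcholine transporter), *Gad1* (GABA synthesis) or *VGlut* (vesicular
    glutamate transporter) exceeds its threshold (0.5 / 0.4 / 0.5) gets that
    class; none above gives ``unknown``, more than one ``ambiguous``.
    """
    thresholds = thresholds or NT_THRESHOLDS
    missing = [g for g in thresholds if g not in adata.var_names]
    if missing:
        raise KeyError(f"marker gene(s) {missing} absent from the matrix")
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    above = np.column_stack([
        X[:, adata.var_names.get_loc(g)] > thr for g, thr in thresholds.items()
    ])
    classes = [NT_CLASSES.get(g, g) for g in thresholds]
    n_above = above.sum(axis=1)
    out = np.where(
        n_above == 0, "unknown",
        np.where(n_above > 1, "ambiguous",
                 np.array(classes, dtype=object)[np.argmax(above, axis=1)]),
    )
    return pd.Series(out, index=adata.obs_names, name="neurotransmitter")
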