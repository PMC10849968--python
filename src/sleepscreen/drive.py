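"""Sleep-drive template matching.

Conditions are ordered by the amount of sleep pressure the animals
experienced and mapped to evenly spaced template values on [0, 1] (0 =
lowest pressure, 1 = highest).  Within each eligible cluster, every gene's
per-condition mean expression is Pearson-correlated with the template; the
two-tailed p-value (k - 2 degrees of freedom over the k condition points) is
BH-corrected across the cluster's genes.  Both positively and negatively
correlated genes count as sleep-drive correlates.  A cluster is eligible
only when every ranked condition has at least ``min_cells_per_condition``
cells, mirroring how condition-mean matrix generation can fail for sparse
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .design import ConditionDesign, build_template
from .preprocess import cluster_condition_means

__all__ = ["DriveParams", "DriveScreen", "DriveResults", "correlate_overlap"]


@dataclass
class DriveParams:
    alpha: float = 0.05
    min_cells_per_condition: int = 3

    def __post_init__(self) -> None:
        if self.min_cells_per_condition < 1:
            raise ValueError("min_cells_per_condition must be >= 1")


class DriveResults:
    """Per-(cluster, gene) template correlations."""

    def __init__(self, table: pd.DataFrame, ineligible: dict[str, str], params: DriveParams):
        self.table = table
        self.ineligible = ineligible
        self.params = params

    @property
    def n_correlates(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=int)
        return self.table.groupby("cluster", observed=True)["is_correlate"].sum().astype(int)

    def correlates(self, cluster: str) -> set[str]:
        t = self.table
        return set(t.loc[(t["cluster"] == cluster) & t["is_correlate"], "gene"])

    def summary(self) -> pd.DataFrame:
        out = self.table.groupby("cluster", observed=True).agg(
            n_tested=("tested", "sum"), n_correlates=("is_correlate", "sum")
        )
        return out.reset_index()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class DriveScreen:
    """Template-matching screen for sleep-drive correlates.

    Parameters
    ----------
    adata : AnnData
        Log-normalized dataset (``cluster`` and ``condition`` in ``.obs``).
    design : ConditionDesign
        Must contain >= 2 drive-ranked conditions.
    """

    def __init__(self, adata: ad.AnnData, design: ConditionDesign,
                 params: DriveParams | None = None, clusters=None, gene_mask=None):
        self.adata = adata
        self.design = design
        self.params = params or DriveParams()
        self.clusters = [str(c) for c in (
            clusters if clusters is not None else adata.obs["cluster"].astype(str).unique()
        )]
        self.gene_mask = gene_mask

    def fit(self) -> DriveResults:
        params = self.params
        template = build_template(self.design)
        cond_names = [name for name, _ in template]
        t_values = np.array([v for _, v in template])
        genes = self.adata.var_names.to_numpy()
        keep = np.ones(len(genes), dtype=bool)
        if self.gene_mask is not None:
            keep &= ~self.gene_mask.reindex(self.adata.var_names, fill_value=False).to_numpy()

        tables = []
        ineligible: dict[str, str] = {}
        for cl in self.clusters:
            means, counts = cluster_condition_means(self.adata, cl)
            low = [c for c in cond_names
                   if counts.get(c, 0) < params.min_cells_per_condition]
            if low:
                ineligible[cl] = (
                    f"conditions {low} have < {params.min_cells_per_condition} cells"
                )
                continue
            m = means[cond_names].to_numpy()  # genes x k
            r, p = _pearson_vs_template(m, t_values)
            tested = keep & np.isfinite(r)
            p = np.where(tested, p, 1.0)
            p_bh = np.full(len(genes), np.nan)
            if tested.any():
                p_bh[tested] = multipletests(p[tested], method="fdr_bh")[1]
            is_corr = np.zeros(len(genes), dtype=bool)
            is_corr[tested] = p_bh[tested] < params.alpha
            tables.append(pd.DataFrame({
                "cluster": cl,
                "gene": genes,
                "tested": tested,
                "r": np.where(tested, r, np.nan),
                "p": p,
                "p_bh": p_bh,
                "is_correlate": is_corr,
            }))
        table = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["cluster", "gene", "tested", "r", "p", "p_bh",
                                       "is_correlate"])
        )
        return DriveResults(table, ineligible, params)


def _pearson_vs_template(m: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of ``m`` (genes x k) against ``t`` and two-tailed p.

    Constant rows get ``r = nan``; the p-value uses the t-distribution with
    k - 2 degrees of freedom.
    """
    k = t.size
    mc = m - m.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    sm = np.sqrt((mc**2).sum(axis=1))
    stt = np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ tc) / (sm * stt)
    r = np.where(sm > 0, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((k - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * st.t.sf(np.abs(tstat), df=k - 2)
    p = np.where(np.isfinite(r), np.minimum(p, 1.0), 1.0)
    return r, p


def correlate_overlap(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Row-normalized overlap grid between per-cluster gene sets.

    Entry (A, B) = |set(A) ∩ set(B)| / |set(A)|; asymmetric.  Clusters with
    empty sets are dropped (at least two non-empty sets required).
    """
    keys = [k for k, s in gene_sets.items() if s]
    if len(keys) < 2:
        raise ValueError("need >= 2 clusters with non-empty gene sets")
    grid = pd.DataFrame(0.0, index=keys, columns=keys)
    for a in keys:
        for b in keys:
            grid.loc[a, b] = len(gene_sets[a] & gene_sets[b]) / len(gene_sets[a])
    return grid
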