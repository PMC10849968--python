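"""Exact nonparametric rhythm detection (JTK) with pseudo-replicate consensus.

The test rank-correlates a gene's expression against a 24-h cosine reference
discretized at the sampled ZT times.  Because every pseudo-replicate at the
same ZT shares one reference value, the reference has tie groups, and the
Kendall score

    S = sum over pairs (i < j) of sign(x_i - x_j) * sign(ref_i - ref_j)

only counts pairs across ZT groups.  Under permutation of the data values,
S is (up to the affine map ``S = 2J - M``) the Jonckheere–Terpstra-type
statistic of the groups sorted by reference value, whose exact null
distribution is given by the Gaussian (q-)multinomial coefficient: the
generating function over arrangements factorizes into Gaussian binomials,
which we build by q-Pascal convolution.  The two-tailed p-value is
``P(|S_null| >= |S_obs|)``.

Single cells are too noisy to feed the rank test one by one, so each
cluster's cells are randomly partitioned into pseudo-replicates per ZT,
whose mean expression forms the test input.  The random allocation is
repeated (three times by default) and a gene is called a cycler only when
significant (BH-corrected) in every allocation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "JtkParams",
    "ExactKendallNull",
    "cosine_reference",
    "kendall_s",
    "jtk_exact_test",
    "make_pseudo_replicates",
    "prefilter_genes",
    "CyclingScreen",
    "CyclingResults",
]


@dataclass
class JtkParams:
    """Settings of the consensus cycling screen."""

    period: float = 24.0
    timepoints: tuple[float, ...] = (2.0, 8.0, 14.0, 20.0)
    n_pseudo_reps: int = 3
    n_allocations: int = 3
    min_cpm: float = 0.8
    min_fold: float = 1.5
    alpha: float = 0.05
    lags: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pseudo_reps < 2:
            raise ValueError("n_pseudo_reps must be >= 2")
        if any(not 0 <= l < self.period for l in self.lags):
            raise ValueError("lags must lie in [0, period)")


def _q_binomial(a: int, b: int) -> np.ndarray:
    """Coefficients of the Gaussian binomial [a+b choose b]_q (length a*b+1).

    Built with the q-Pascal recurrence
    ``[a+b, b]_q = [a+b-1, b-1]_q + q^b * [a+b-1, b]_q``.
    Coefficient k counts the interleavings of two blocks of sizes a and b
    with exactly k inversions between blocks.
    """
    table = {(i, 0): np.ones(1) for i in range(a + 1)}
    for j in range(1, b + 1):
        table[(0, j)] = np.ones(1)
    for i in range(1, a + 1):
        for j in range(1, b + 1):
            left = table[(i, j - 1)]
            up = table[(i - 1, j)]
            out = np.zeros(i * j + 1)
            out[: left.size] += left
            out[j : j + up.size] += up
            table[(i, j)] = out
    return table[(a, b)]


@lru_cache(maxsize=64)
def _null_distribution(group_sizes: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """Null counts of J (concordant cross-group exceedances) and max S.

    For reference tie-groups of the given sizes, returns the array
    ``counts[j] = #arrangements with J = j`` (J in 0..M, M = sum_{i<j} n_i n_j)
    and M itself; S = 2J - M.
    """
    counts = np.ones(1)
    m = 0
    for n in group_sizes:
        counts = np.convolve(counts, _q_binomial(m, n))
        m += n
    M = counts.size - 1
    return counts, M


class ExactKendallNull:
    """Exact two-tailed null of the Kendall score S for a reference tie structure."""

    def __init__(self, group_sizes) -> None:
        sizes = tuple(int(n) for n in group_sizes)
        if any(n < 1 for n in sizes):
            raise ValueError("group sizes must be >= 1")
        counts, self.max_s = _null_distribution(sizes)
        self._total = counts.sum()
        # tail[j] = P(J >= j); by symmetry P(J <= M - j) = tail[j]
        self._tail = np.concatenate([np.cumsum(counts[::-1])[::-1], [0.0]]) / self._total

    def p_two_tailed(self, s) -> np.ndarray | float:
        """P(|S_null| >= |s|) with S = 2J - M."""
        s = np.abs(np.asarray(s, dtype=float))
        if np.any(s > self.max_s):
            raise ValueError("|S| exceeds the maximum attainable score")
        j_hi = np.ceil((self.max_s + s) / 2.0).astype(int)
        upper = self._tail[j_hi]
        lower = self._tail[np.where(s > 0, j_hi, self.max_s + 1)]  # P(J <= M - j_hi)
        p = np.minimum(upper + lower, 1.0)
        p = np.where(s == 0, 1.0, p)
        return p if p.ndim else float(p)


def cosine_reference(zts, lag: float, period: float = 24.0) -> np.ndarray:
    """Cosine reference waveform, peaking at ``lag`` hours, evaluated at the ZTs."""
    zts = np.asarray(zts, dtype=float)
    return np.cos(2.0 * np.pi * (zts - lag) / period)


def kendall_s(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Kendall score S of each row of ``values`` against ``ref``.

    Pairs tied in the reference (same ZT group) contribute zero; pairs tied
    in the data contribute zero.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ref = np.asarray(ref, dtype=float)
    n = ref.size
    iu, ju = np.triu_indices(n, k=1)
    ref_sign = np.sign(ref[iu] - ref[ju])
    keep = ref_sign != 0
    dv = np.sign(values[:, iu[keep]] - values[:, ju[keep]])
    return (dv * ref_sign[keep]).sum(axis=1).astype(int)


def _tie_pairs(values: np.ndarray) -> np.ndarray:
    """Number of tied pairs per row."""
    values = np.atleast_2d(values)
    n = values.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return (values[:, iu] == values[:, ju]).sum(axis=1)


def jtk_exact_test(
    values: np.ndarray,
    zts: np.ndarray,
    params: JtkParams | None = None,
) -> pd.DataFrame:
    """Exact JTK over all lags for one or more genes.

    Parameters
    ----------
    values : (n_genes, n_obs) or (n_obs,) array
        Observations (pseudo-replicate means); column ``i`` was measured at
        ``zts[i]``.
    zts : (n_obs,) array
        ZT time of each observation.

    Returns a DataFrame with columns ``S`` (score at the best lag), ``tau``
    (tie-corrected Kendall correlation at the best lag), ``best_lag``,
    ``p_exact`` (two-tailed exact p at the best lag) and ``p_adj_lags``
    (Bonferroni over the lag set, capped at 1).  Rows of constant values get
    ``p = 1``.
    """
    params = params or JtkParams()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    zts = np.asarray(zts, dtype=float)
    if values.shape[1] != zts.size:
        raise ValueError("values and zts are misaligned")
    if np.unique(zts).size < 2:
        raise ValueError("need >= 2 distinct timepoints")

    n_genes = values.shape[0]
    n_lags = len(params.lags)
    s_all = np.empty((n_lags, n_genes), dtype=int)
    p_all = np.empty((n_lags, n_genes))
    t_ref_all = np.empty(n_lags)
    for li, lag in enumerate(params.lags):
        ref = np.round(cosine_reference(zts, lag, params.period), 12)
        sizes = np.bincount(np.unique(ref, return_inverse=True)[1])
        null = ExactKendallNull(tuple(sorted(sizes)))
        s_all[li] = kendall_s(values, ref)
        p_all[li] = null.p_two_tailed(s_all[li])
        t_ref_all[li] = (sizes * (sizes - 1) // 2).sum()

    # best lag: smallest p, ties broken toward the largest (most in-phase) S
    p_exact = p_all.min(axis=0)
    s_masked = np.where(p_all == p_exact[None, :], s_all, np.iinfo(np.int64).min)
    best_idx = np.argmax(s_masked, axis=0)
    s_best = s_all[best_idx, np.arange(n_genes)]
    p_adj = np.minimum(1.0, p_exact * n_lags)

    # tie-corrected tau at the best lag
    n = zts.size
    n0 = n * (n - 1) / 2.0
    t_v = _tie_pairs(values)
    t_ref = t_ref_all[best_idx]
    denom = np.sqrt(np.maximum(n0 - t_v, 0) * np.maximum(n0 - t_ref, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(denom > 0, s_best / denom, 0.0)
    constant = t_v == n0
    p_exact = np.where(constant, 1.0, p_exact)
    p_adj = np.where(constant, 1.0, p_adj)

    return pd.DataFrame(
        {
            "S": s_best,
            "tau": tau,
            "best_lag": np.asarray(params.lags)[best_idx],
            "p_exact": p_exact,
            "p_adj_lags": p_adj,
        }
    )


class IneligibleClusterError(ValueError):
    """The cluster lacks enough cells at some ZT to form pseudo-replicates."""


def make_pseudo_replicates(
    adata: ad.AnnData,
    cluster: str,
    params: JtkParams,
    allocation_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Random partition of a cluster's cells into pseudo-replicates per ZT.

    Returns ``(rep_means, rep_zts)``: a genes x (n_zt * n_reps) matrix of
    mean log-normalized expression and the ZT of each column.  Every cell
    appears in exactly one pseudo-replicate of its own ZT.  Raises
    :class:`IneligibleClusterError` when any ZT has fewer cells than
    pseudo-replicates.
    """
    rng = np.random.default_rng(allocation_seed)
    in_cluster = (adata.obs["cluster"].astype(str) == str(cluster)).to_numpy()
    zt = pd.to_numeric(adata.obs["zt"], errors="coerce").to_numpy(dtype=float)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)

    cols = []
    col_zts = []
    for t in params.timepoints:
        cells = np.flatnonzero(in_cluster & (zt == t))
        if cells.size < params.n_pseudo_reps:
            raise IneligibleClusterError(
                f"cluster {cluster!r} has {cells.size} cells at ZT{t:g}, "
                f"needs >= {params.n_pseudo_reps}"
            )
        perm = rng.permutation(cells)
        for r in range(params.n_pseudo_reps):
            members = perm[r :: params.n_pseudo_reps]
            cols.append(np.asarray(X[members].mean(axis=0)).ravel())
            col_zts.append(t)
    return np.column_stack(cols), np.asarray(col_zts, dtype=float)


def zt_mean_cpm(adata: ad.AnnData, cluster: str, params: JtkParams) -> np.ndarray:
    """Per-ZT mean CPM over the cluster's cells (genes x n_zt)."""
    in_cluster = (adata.obs["cluster"].astype(str) == str(cluster)).to_numpy()
    zt = pd.to_numeric(adata.obs["zt"], errors="coerce").to_numpy(dtype=float)
    cpm = adata.layers["cpm"]
    if not sp.issparse(cpm):
        cpm = sp.csr_matrix(cpm)
    cols = []
    for t in params.timepoints:
        cells = np.flatnonzero(in_cluster & (zt == t))
        if cells.size == 0:
            raise IneligibleClusterError(f"cluster {cluster!r} has no cells at ZT{t:g}")
        cols.append(np.asarray(cpm[cells].mean(axis=0)).ravel())
    return np.column_stack(cols)


def prefilter_genes(zt_cpm: np.ndarray, params: JtkParams) -> np.ndarray:
    """Expression and amplitude filter on per-ZT mean CPM.

    A gene is tested iff its maximum per-ZT mean CPM is at least ``min_cpm``
    and the max/min ratio across ZTs is at least ``min_fold`` (pseudocount
    1e-9 on the denominator).
    """
    hi = zt_cpm.max(axis=1)
    lo = zt_cpm.min(axis=1)
    fold = hi / (lo + 1e-9)
    return (hi >= params.min_cpm) & (fold >= params.min_fold)


class CyclingResults:
    """Per-(cluster, gene) cycling calls from :class:`CyclingScreen`."""

    def __init__(self, table: pd.DataFrame, ineligible: dict[str, str], params: JtkParams):
        self.table = table
        self.ineligible = ineligible
        self.params = params

    @property
    def n_cyclers(self) -> pd.Series:
        """Consensus cycler count per eligible cluster."""
        if self.table.empty:
            return pd.Series(dtype=int)
        return self.table.groupby("cluster", observed=True)["is_cycler"].sum().astype(int)

    def cyclers(self, cluster: str) -> set[str]:
        t = self.table
        return set(t.loc[(t["cluster"] == cluster) & t["is_cycler"], "gene"])

    def summary(self) -> pd.DataFrame:
        rows = []
        for cl, grp in self.table.groupby("cluster", observed=True):
            rows.append({
                "cluster": cl,
                "n_tested": int(grp["tested"].sum()),
                "n_cyclers": int(grp["is_cycler"].sum()),
            })
        for cl, why in self.ineligible.items():
            rows.append({"cluster": cl, "n_tested": 0, "n_cyclers": pd.NA})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class CyclingScreen:
    """Consensus JTK cycling screen over the clusters of a normalized dataset.

    Parameters
    ----------
    adata : AnnData
        Output of :func:`sleepscreen.preprocess.normalize` (log-normalized
        ``.X`` plus a ``cpm`` layer), with ``cluster`` and ``zt`` in ``.obs``.
    params : JtkParams
    clusters : iterable of str, optional
        Subset of clusters to screen (default: all).
    gene_mask : boolean Series indexed by gene, optional
        Genes to exclude (e.g. run-effect genes).
    """

    def __init__(self, adata, params: JtkParams | None = None, clusters=None, gene_mask=None):
        self.adata = adata
        self.params = params or JtkParams()
        self.clusters = [str(c) for c in (
            clusters if clusters is not None else adata.obs["cluster"].astype(str).unique()
        )]
        self.gene_mask = gene_mask

    def fit(self) -> CyclingResults:
        params = self.params
        genes = self.adata.var_names.to_numpy()
        keep_genes = np.ones(len(genes), dtype=bool)
        if self.gene_mask is not None:
            keep_genes &= ~self.gene_mask.reindex(self.adata.var_names, fill_value=False).to_numpy()

        seeds = np.random.default_rng(params.seed).integers(2**31, size=params.n_allocations)
        tables = []
        ineligible: dict[str, str] = {}
        for cl in self.clusters:
            try:
                cpm = zt_mean_cpm(self.adata, cl, params)
                rep_sets = [
                    make_pseudo_replicates(self.adata, cl, params, int(s)) for s in seeds
                ]
            except IneligibleClusterError as e:
                ineligible[cl] = str(e)
                continue
            tested = prefilter_genes(cpm, params) & keep_genes
            idx = np.flatnonzero(tested)
            amp = cpm.max(axis=1) / (cpm.min(axis=1) + 1e-9)

            n = len(genes)
            p_bh = np.full((params.n_allocations, n), np.nan)
            sig = np.zeros((params.n_allocations, n), dtype=bool)
            first_stats = None
            for a, (rep_means, rep_zts) in enumerate(rep_sets):
                if idx.size == 0:
                    continue
                res = jtk_exact_test(rep_means[idx], rep_zts, params)
                adj = multipletests(res["p_adj_lags"].to_numpy(), method="fdr_bh")[1]
                p_bh[a, idx] = adj
                sig[a, idx] = adj < params.alpha
                if a == 0:
                    first_stats = res
            is_cycler = sig.all(axis=0)

            tab = pd.DataFrame({
                "cluster": cl,
                "gene": genes,
                "tested": tested,
                "S": np.nan, "tau": np.nan, "best_lag": np.nan,
                "p_exact": np.nan, "p_adj_lags": np.nan,
                "amplitude_fold": amp,
                "is_cycler": is_cycler,
            })
            if first_stats is not None and idx.size:
                for col in ("S", "tau", "best_lag", "p_exact", "p_adj_lags"):
                    tab.loc[tab.index[idx], col] = first_stats[col].to_numpy()
            for a in range(params.n_allocations):
                tab[f"p_bh_alloc{a + 1}"] = p_bh[a]
            tables.append(tab)

        table = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["cluster", "gene", "tested", "is_cycler"])
        )
        return CyclingResults(table, ineligible, params)
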