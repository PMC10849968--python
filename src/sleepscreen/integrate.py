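"""Process assignment and reference-matching annotation.

Borbély's two-process model distinguishes the circadian clock (process C)
from the sleep homeostat (process S).  Each cell population is assigned to
one, both or neither process by comparing, on the square-root scale, its
number of cycling transcripts and of sleep-drive correlates against
data-derived thresholds: the threshold for each process is the mean of
``sqrt(count)`` over the clusters eligible for that screen, and a cluster is
assigned when its own ``sqrt(count)`` strictly exceeds the threshold.

The annotation utility matches external expression profiles (e.g. sorted
dFB neurons profiled with a plate-based protocol) to cluster centroids by
non-negative least squares, restricted to the union of each cluster's top
marker genes by z-score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "assign_processes",
    "ProcessAssignment",
    "top_marker_panel",
    "nnls_match",
    "AnnotationResult",
    "correlate_summary",
]


@dataclass
class ProcessAssignment:
    """Per-cluster process labels plus the thresholds they were derived from."""

    table: pd.DataFrame  # cluster, n_cyclers, n_drive, label
    threshold_cyclers: float
    threshold_drive: float

    def labels(self) -> pd.Series:
        return self.table.set_index("cluster")["label"]

    def summary(self) -> pd.DataFrame:
        return self.table


def assign_processes(
    cycler_counts: pd.Series,
    drive_counts: pd.Series,
) -> ProcessAssignment:
    """Assign clusters to circadian / sleep-drive processes.

    Parameters
    ----------
    cycler_counts, drive_counts : Series indexed by cluster
        Consensus cycler and drive-correlate counts over the clusters
        *eligible* for each screen; the two indexes may differ.  Each
        threshold is the mean of ``sqrt(count)`` over its own eligible
        universe.  A cluster receives a four-way label only if it is
        eligible for both screens; otherwise its label is ``NA``.

    Raises
    ------
    ValueError
        If either eligible-cluster set is empty or any count is negative.
    """
    for name, counts in (("cycler", cycler_counts), ("drive", drive_counts)):
        if len(counts) == 0:
            raise ValueError(f"empty {name} eligible-cluster set")
        if (np.asarray(counts) < 0).any():
            raise ValueError(f"negative {name} count")

    t_c = float(np.sqrt(cycler_counts.astype(float)).mean())
    t_s = float(np.sqrt(drive_counts.astype(float)).mean())

    clusters = sorted(set(cycler_counts.index) | set(drive_counts.index))
    rows = []
    for cl in clusters:
        nc = cycler_counts.get(cl, pd.NA)
        nd = drive_counts.get(cl, pd.NA)
        if pd.isna(nc) or pd.isna(nd):
            label = pd.NA
        else:
            c_hit = np.sqrt(float(nc)) > t_c
            s_hit = np.sqrt(float(nd)) > t_s
            label = {
                (True, True): "both",
                (True, False): "cyclers",
                (False, True): "drive",
                (False, False): "neither",
            }[(c_hit, s_hit)]
        rows.append({"cluster": cl, "n_cyclers": nc, "n_drive": nd, "label": label})
    table = pd.DataFrame(rows)
    return ProcessAssignment(table, t_c, t_s)


def top_marker_panel(centroids: pd.DataFrame, panel_size: int = 10) -> list[str]:
    """Union over clusters of the top ``panel_size`` marker genes by z-score.

    ``centroids`` is genes x clusters; the marker z-score of gene g in
    cluster c is ``(centroid[g, c] - mean_c centroid[g, .]) / sd_c`` with the
    standard deviation taken across clusters (genes constant across clusters
    score 0).
    """
    if centroids.shape[1] < 2:
        raise ValueError("reference must have >= 2 clusters")
    m = centroids.to_numpy(dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (m - mu) / sd, 0.0)
    panel: set[str] = set()
    for j in range(m.shape[1]):
        order = np.argsort(z[:, j])[::-1][:panel_size]
        panel |= set(centroids.index[order])
    return sorted(panel)


@dataclass
class AnnotationResult:
    """NNLS match of one query profile against cluster centroids."""

    best_match: str | None  # None when all coefficients are zero
    coefficients: pd.Series  # non-negative, indexed by cluster
    residual: float
    panel: list[str]

    @property
    def assigned(self) -> bool:
        return self.best_match is not None


def nnls_match(
    query: pd.Series,
    centroids: pd.DataFrame,
    marker_panel_size: int = 10,
) -> AnnotationResult:
    """Match a query expression profile to reference cluster centroids.

    Non-negative least squares of the query on the centroid columns,
    restricted to the union of each cluster's top ``marker_panel_size``
    marker genes by z-score.  The best match is the cluster with the largest
    coefficient; a query orthogonal to all centroids on the panel (all
    coefficients zero) is returned unassigned.

    Raises
    ------
    ValueError
        If the query is missing more than half of the panel genes.
    """
    panel = top_marker_panel(centroids, marker_panel_size)
    present = [g for g in panel if g in query.index and np.isfinite(query[g])]
    if len(present) < 0.5 * len(panel):
        raise ValueError(
            f"query covers only {len(present)}/{len(panel)} panel genes (> 50% required)"
        )
    A = centroids.loc[present].to_numpy(dtype=float)
    b = query[present].to_numpy(dtype=float)
    coef, resid = scipy.optimize.nnls(A, b)
    coefficients = pd.Series(coef, index=centroids.columns, name="coefficient")
    if np.all(coef == 0):
        best = None
    else:
        top = coefficients[coefficients == coefficients.max()]
        if len(top) == 1:
            best = str(top.index[0])
        else:
            # tie on the coefficient: keep the component whose lone centroid
            # explains the query with the smaller residual
            resids = {
                c: float(np.linalg.norm(b - A[:, centroids.columns.get_loc(c)] * coef[centroids.columns.get_loc(c)]))
                for c in top.index
            }
            best = min(resids, key=resids.get)
    return AnnotationResult(best, coefficients, float(resid), panel)


def correlate_summary(
    cycling_results=None,
    drive_results=None,
    deg_results=None,
) -> pd.DataFrame:
    """Tidy per-cluster summary across all screens — the headline output.

    One row per cluster with counts of consensus cyclers, sleep-drive
    correlates and DEGs (``NA`` where the cluster was ineligible for or
    skipped by a screen), per-screen eligibility flags, and the four-way
    process label (computed only for clusters eligible for both the cycling
    and the drive screen).

    Raises
    ------
    ValueError
        If no screen results are supplied.
    """
    if cycling_results is None and drive_results is None and deg_results is None:
        raise ValueError("no screen results supplied")

    clusters: set[str] = set()
    pieces: dict[str, pd.Series] = {}
    flags: dict[str, set[str]] = {}

    if cycling_results is not None:
        pieces["n_cyclers"] = cycling_results.n_cyclers
        flags["cycling_eligible"] = set(pieces["n_cyclers"].index)
        clusters |= flags["cycling_eligible"] | set(cycling_results.ineligible)
    if drive_results is not None:
        pieces["n_drive"] = drive_results.n_correlates
        flags["drive_eligible"] = set(pieces["n_drive"].index)
        clusters |= flags["drive_eligible"] | set(drive_results.ineligible)
    if deg_results is not None:
        pieces["n_deg"] = deg_results.n_deg
        flags["dea_eligible"] = set(pieces["n_deg"].index)
        clusters |= flags["dea_eligible"] | set(deg_results.skipped)
    if not clusters:
        raise ValueError("no clusters in any screen result")

    out = pd.DataFrame({"cluster": sorted(clusters)}).set_index("cluster")
    for col, series in pieces.items():
        out[col] = series.reindex(out.index).astype("Int64")
    for col, elig in flags.items():
        out[col] = out.index.isin(sorted(elig))

    if (
        cycling_results is not None
        and drive_results is not None
        and len(pieces["n_cyclers"])
        and len(pieces["n_drive"])
    ):
        assignment = assign_processes(pieces["n_cyclers"], pieces["n_drive"])
        out["label"] = assignment.labels().reindex(out.index)
        out.attrs["threshold_cyclers"] = assignment.threshold_cyclers
        out.attrs["threshold_drive"] = assignment.threshold_drive
    return out.reset_index()
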