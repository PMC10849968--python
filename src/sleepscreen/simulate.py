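"""Synthetic droplet-count generator with planted circadian and sleep signals.

Counts are negative-binomial (gamma–Poisson) with log-normal per-cell library
sizes.  Within each cluster, four disjoint gene sets can be planted:

* **cyclers** — the mean is modulated multiplicatively by a 24-h cosine at
  the cell's ZT, ``mean * (1 + a*cos(2*pi*(zt - phase)/24))`` with
  ``a = (fold - 1)/(fold + 1)`` so that the peak/trough ratio equals the
  planted fold;
* **drive genes** — the log-mean increases linearly with the cell's
  condition value on the 0-1 sleep-pressure template (``mean * exp(slope*d)``);
* **DEGs** — the mean is shifted by ``2**deg_logfc`` in the pooled sleep
  group relative to wake;
* **markers** — elevated ``marker_fold``-fold in their own cluster.

Doublets are simulated as the count-sum of two random same-genotype cells
and flagged in the returned truth object.  Everything is reproducible from
the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .design import ConditionDesign, build_template, default_design

__all__ = ["SyntheticDesign", "SyntheticTruth", "expected_doublet_rate", "generate_dataset"]

PerCluster = Union[int, Sequence[int]]


def expected_doublet_rate(n_cells: int, num_lines: int) -> float:
    """Expected residual within-genotype doublet fraction.

    Droplet devices produce doublets at roughly 0.8% per 1,000 cells loaded;
    genotype demultiplexing removes the between-line share, leaving a
    fraction ``0.008 * (n_cells / 1000) * (num_lines / num_lines**2)``
    = ``0.008 * (n_cells / 1000) / num_lines``.
    """
    if num_lines < 1:
        raise ValueError(f"num_lines must be >= 1, got {num_lines}")
    if n_cells < 0:
        raise ValueError(f"n_cells must be >= 0, got {n_cells}")
    return 0.008 * (n_cells / 1000.0) / num_lines


@dataclass
class SyntheticDesign:
    """Parameters of a synthetic dataset.

    Per-cluster planted-gene counts (``n_cyclers_per_cluster`` etc.) may be a
    single int (same in every cluster) or a sequence of length ``n_clusters``.
    ``doublet_fraction=None`` uses :func:`expected_doublet_rate` for the
    generated cell number and ``n_genotypes``.
    """

    n_clusters: int = 3
    cells_per_cluster_condition: int = 50
    n_genes: int = 1000
    baseline_mean: float = 0.5
    nb_dispersion: float = 10.0
    n_cyclers_per_cluster: PerCluster = 0
    cycler_fold: float = 3.0
    cycler_phases: Sequence[float] = (0.0, 6.0, 12.0, 18.0)
    n_drive_genes_per_cluster: PerCluster = 0
    drive_slope: float = 1.0
    n_deg_per_cluster: PerCluster = 0
    deg_logfc: float = 1.0
    n_markers_per_cluster: PerCluster = 0
    marker_fold: float = 8.0
    doublet_fraction: Optional[float] = 0.0
    n_genotypes: int = 2
    n_runs: int = 2
    library_sigma: float = 0.3
    shared_deg_genes: bool = False
    seed: int = 0
    design: ConditionDesign = field(default_factory=default_design)

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be >= 0")
        if self.cycler_fold < 1 or self.marker_fold < 1:
            raise ValueError("fold parameters must be >= 1")
        if self.doublet_fraction is not None and not 0 <= self.doublet_fraction < 1:
            raise ValueError("doublet_fraction must be in [0, 1)")
        for attr in ("n_cyclers_per_cluster", "n_drive_genes_per_cluster",
                     "n_deg_per_cluster", "n_markers_per_cluster"):
            val = getattr(self, attr)
            if not np.isscalar(val) and len(val) != self.n_clusters:
                raise ValueError(f"{attr} sequence must have length n_clusters")

    def per_cluster(self, attr: str) -> list[int]:
        val = getattr(self, attr)
        if np.isscalar(val):
            return [int(val)] * self.n_clusters
        return [int(v) for v in val]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset: planted gene sets per cluster."""

    cycler_genes: dict[str, list[str]]
    drive_genes: dict[str, list[str]]
    deg_genes: dict[str, list[str]]
    marker_genes: dict[str, list[str]]
    gene_params: pd.DataFrame  # per planted gene: cluster, role, phase/fold/slope/logfc
    doublets: list[tuple[str, str, str]]  # (doublet_id, parent1, parent2)

    def planted(self, cluster: str, role: str) -> set[str]:
        return set(getattr(self, f"{role}_genes").get(cluster, []))


def _plant_gene_sets(design: SyntheticDesign, rng: np.random.Generator):
    """Choose pairwise-disjoint (within cluster) gene index sets per role."""
    clusters = [f"c{i}" for i in range(design.n_clusters)]
    counts = {
        "cycler": design.per_cluster("n_cyclers_per_cluster"),
        "drive": design.per_cluster("n_drive_genes_per_cluster"),
        "deg": design.per_cluster("n_deg_per_cluster"),
        "marker": design.per_cluster("n_markers_per_cluster"),
    }
    sets: dict[str, dict[str, np.ndarray]] = {r: {} for r in counts}
    shared_deg: np.ndarray | None = None
    pool = np.arange(design.n_genes)
    if design.shared_deg_genes:
        k = max(counts["deg"], default=0)
        if any(c not in (0, k) for c in counts["deg"]):
            raise ValueError("shared_deg_genes requires equal n_deg_per_cluster")
        if k > design.n_genes:
            raise ValueError("too few genes for the shared DEG set")
        shared_deg = np.sort(rng.choice(design.n_genes, size=k, replace=False))
        pool = np.setdiff1d(pool, shared_deg)
    for ci, cl in enumerate(clusters):
        roles = ("cycler", "drive", "marker") if shared_deg is not None else (
            "cycler", "drive", "deg", "marker")
        need = sum(counts[r][ci] for r in roles)
        if need > pool.size:
            raise ValueError(
                f"cluster {cl} needs {need} disjoint planted genes but only "
                f"{pool.size} are available"
            )
        chosen = rng.choice(pool, size=need, replace=False)
        offset = 0
        for role in roles:
            k = counts[role][ci]
            sets[role][cl] = np.sort(chosen[offset : offset + k])
            offset += k
        if shared_deg is not None:
            sets["deg"][cl] = shared_deg if counts["deg"][ci] else np.array([], dtype=int)
    return clusters, sets


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[ad.AnnData, ConditionDesign, SyntheticTruth]:
    """Generate counts, metadata and ground truth for one synthetic study.

    Returns an AnnData of raw integer counts (cells x genes) with ``obs``
    columns ``cluster``, ``condition``, ``zt``, ``genotype``, ``run`` and
    ``is_doublet``, the condition design used, and the truth object.
    """
    rng = np.random.default_rng(design.seed)
    cdesign = design.design
    clusters, sets = _plant_gene_sets(design, rng)
    gene_ids = np.array([f"g{i:05d}" for i in range(design.n_genes)])

    template = dict(build_template(cdesign)) if len(cdesign.ranked_conditions) >= 2 else {}
    amp = (design.cycler_fold - 1.0) / (design.cycler_fold + 1.0)
    phases = np.asarray(design.cycler_phases, dtype=float)

    # per-gene parameter bookkeeping
    records = []
    for cl in clusters:
        for j, gi in enumerate(sets["cycler"][cl]):
            records.append((cl, gene_ids[gi], "cycler",
                            float(phases[j % len(phases)]), design.cycler_fold))
        for gi in sets["drive"][cl]:
            records.append((cl, gene_ids[gi], "drive", np.nan, design.drive_slope))
        for gi in sets["deg"][cl]:
            records.append((cl, gene_ids[gi], "deg", np.nan, design.deg_logfc))
        for gi in sets["marker"][cl]:
            records.append((cl, gene_ids[gi], "marker", np.nan, design.marker_fold))
    gene_params = pd.DataFrame(
        records, columns=["cluster", "gene", "role", "phase", "effect"]
    )

    # cell metadata
    obs_rows = []
    for cl in clusters:
        for cond in cdesign.conditions:
            for _ in range(design.cells_per_cluster_condition):
                obs_rows.append((cl, cond.name, cond.zt))
    obs = pd.DataFrame(obs_rows, columns=["cluster", "condition", "zt"])
    n_cells = len(obs)
    obs["genotype"] = [f"line{i % design.n_genotypes}" for i in rng.permutation(n_cells)]
    obs["run"] = [f"run{i % design.n_runs}" for i in rng.permutation(n_cells)]
    obs.index = pd.Index([f"cell{i:06d}" for i in range(n_cells)])

    # per-cell expected means, gene x cell blocks built cluster by cluster
    lib = rng.lognormal(
        mean=-design.library_sigma**2 / 2.0, sigma=design.library_sigma, size=n_cells
    )
    mean = np.full((n_cells, design.n_genes), design.baseline_mean)
    zt = obs["zt"].to_numpy(dtype=float)  # NaN where absent
    cond_template = obs["condition"].map(template).to_numpy(dtype=float)
    in_sleep = obs["condition"].isin(cdesign.sleep_conditions).to_numpy()

    for cl in clusters:
        cells = (obs["cluster"] == cl).to_numpy()
        cyc = sets["cycler"][cl]
        if len(cyc):
            ph = np.array([phases[j % len(phases)] for j in range(len(cyc))])
            mod = 1.0 + amp * np.cos(2 * np.pi * (zt[cells, None] - ph[None, :]) / 24.0)
            mod = np.where(np.isnan(mod), 1.0, mod)
            mean[np.ix_(cells, cyc)] *= mod
        drv = sets["drive"][cl]
        if len(drv):
            d = np.where(np.isnan(cond_template[cells]), 0.0, cond_template[cells])
            mean[np.ix_(cells, drv)] *= np.exp(design.drive_slope * d)[:, None]
        deg = sets["deg"][cl]
        if len(deg):
            mean[np.ix_(cells, deg)] *= np.where(in_sleep[cells], 2.0**design.deg_logfc, 1.0)[:, None]
        mrk = sets["marker"][cl]
        if len(mrk):
            mean[np.ix_(cells, mrk)] *= design.marker_fold

    mean *= lib[:, None]
    theta = design.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam)

    # doublets: sum counts of two same-genotype singlet cells
    frac = design.doublet_fraction
    if frac is None:
        frac = expected_doublet_rate(n_cells, design.n_genotypes)
    doublets: list[tuple[str, str, str]] = []
    if frac > 0:
        n_dbl = int(round(frac * n_cells / (1.0 - frac)))
        dbl_counts = np.zeros((n_dbl, design.n_genes), dtype=counts.dtype)
        dbl_rows = []
        genotypes = obs["genotype"].to_numpy()
        for k in range(n_dbl):
            i = int(rng.integers(n_cells))
            same = np.flatnonzero(genotypes == genotypes[i])
            j = int(rng.choice(same))
            dbl_counts[k] = counts[i] + counts[j]
            did = f"dbl{k:05d}"
            doublets.append((did, obs.index[i], obs.index[j]))
            dbl_rows.append(obs.iloc[i])
        dbl_obs = pd.DataFrame(dbl_rows)
        dbl_obs.index = pd.Index([d[0] for d in doublets])
        counts = np.vstack([counts, dbl_counts])
        obs = pd.concat([obs, dbl_obs])

    obs["is_doublet"] = [False] * n_cells + [True] * (len(obs) - n_cells)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids)),
    )

    truth = SyntheticTruth(
        cycler_genes={cl: list(gene_ids[sets["cycler"][cl]]) for cl in clusters},
        drive_genes={cl: list(gene_ids[sets["drive"][cl]]) for cl in clusters},
        deg_genes={cl: list(gene_ids[sets["deg"][cl]]) for cl in clusters},
        marker_genes={cl: list(gene_ids[sets["marker"][cl]]) for cl in clusters},
        gene_params=gene_params,
        doublets=doublets,
    )
    return adata, cdesign, truth
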