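"""Reading and writing count matrices with per-cell metadata.

On disk a dataset is a directory holding the common sparse exchange layout:
``matrix.mtx`` (genes x cells), ``genes.tsv``, ``barcodes.tsv`` and a
``cell_metadata.tsv`` keyed by barcode with the columns ``cluster``,
``condition`` and optionally ``zt``, ``genotype`` and ``run``.  In memory the
container is an :class:`anndata.AnnData` (cells x genes, the single-cell
convention), with metadata in ``.obs``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .design import Condition, ConditionDesign

__all__ = [
    "FormatError",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
]

REQUIRED_META = ("cluster", "condition")
OPTIONAL_META = ("zt", "genotype", "run")


class FormatError(ValueError):
    """A file on disk is inconsistent with the expected layout."""


def read_counts(path: str | Path) -> ad.AnnData:
    """Load an MTX + sidecar-TSV dataset into an AnnData.

    Raises :class:`FormatError` naming the offending record on dimension
    mismatches, duplicate identifiers or missing metadata columns.
    """
    path = Path(path)
    mtx = scipy.io.mmread(path / "matrix.mtx")
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)

    n_genes, n_cells = mtx.shape
    if len(genes) != n_genes:
        raise FormatError(
            f"genes.tsv has {len(genes)} rows but matrix.mtx has {n_genes} gene rows"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix.mtx has "
            f"{n_cells} cell columns"
        )
    for label, ids in (("gene", genes), ("cell", barcodes)):
        dup = ids[ids.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate {label} id {dup.iloc[0]!r}")

    meta = pd.read_csv(path / "cell_metadata.tsv", sep="\t", dtype={"cell_id": str})
    if "cell_id" not in meta.columns:
        raise FormatError("cell_metadata.tsv lacks a cell_id column")
    missing_cols = [c for c in REQUIRED_META if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"cell_metadata.tsv lacks required columns {missing_cols}")
    meta = meta.set_index("cell_id")
    if meta.index.duplicated().any():
        raise FormatError(
            f"duplicate cell id in metadata: {meta.index[meta.index.duplicated()][0]!r}"
        )
    missing_cells = [b for b in barcodes if b not in meta.index]
    if missing_cells:
        raise FormatError(f"cell {missing_cells[0]!r} has no metadata row")
    meta = meta.loc[barcodes]
    for col in REQUIRED_META:
        if meta[col].isna().any():
            bad = meta.index[meta[col].isna()][0]
            raise FormatError(f"cell {bad!r} has missing {col}")

    X = sp.csr_matrix(mtx.T)  # cells x genes
    if X.nnz and (X.data < 0).any():
        raise FormatError("negative counts in matrix.mtx")
    obs = meta.copy()
    obs.index.name = None
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes.values)))
    adata.obs_names = pd.Index(barcodes.values)
    return adata


def write_counts(adata: ad.AnnData, path: str | Path) -> None:
    """Write an AnnData to the MTX + sidecar layout (genes x cells on disk)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(X.T), field="integer")
    pd.Series(adata.var_names).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    meta = adata.obs.copy()
    meta.insert(0, "cell_id", adata.obs_names)
    meta.to_csv(path / "cell_metadata.tsv", sep="\t", index=False)


def write_design(design: ConditionDesign, path: str | Path) -> None:
    rows = [asdict(c) for c in design.conditions]
    Path(path).write_text(json.dumps(rows, indent=1))


def read_design(path: str | Path) -> ConditionDesign:
    rows = json.loads(Path(path).read_text())
    return ConditionDesign([Condition(**r) for r in rows])


def dump_json(obj, path: str | Path) -> None:
    """Write nested results (truth sets, configs) as JSON."""

    def default(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))
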