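"""Per-subtype sleep/wake classifiers and cross-subtype transfer.

Within a background of related cell subtypes (e.g. glial subtypes or Kenyon
cell subtypes), a separate boosted additive classifier is trained per
subtype to predict the behavioral state (sleep vs wake) of single cells,
after masking subtype marker genes so the models cannot key on cell
identity.  Each model is then evaluated on held-out cells of every subtype;
the transfer grid holds the mean predicted probability of the true label.
A label-shuffle control (labels permuted within subtype before training)
gives the chance-level grid.

The classifier contract is: an additive boosted model over per-gene shape
functions exposing a scalar global importance per gene.  Gradient-boosted
depth-1 stumps satisfy it — the ensemble is a sum of single-feature
functions — and are used here, deterministic given the seed.

The distilled sleep/wake gene list keeps genes whose state-classifier
importance exceeds mean + 2 s.d. over all features, removes genes that also
exceed the same threshold in a control classifier trained to predict
subtype identity, and intersects the remainder with the DEA-significant
genes of the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import train_test_split

from .dea import group_log2_fc

__all__ = [
    "TransferParams",
    "exclude_subtype_markers",
    "train_state_classifier",
    "importance_threshold",
    "filter_state_genes",
    "StateTransfer",
    "TransferResults",
]

MARKER_CUTS = {"glia": 3.5, "KC": 2.0}


@dataclass
class TransferParams:
    background: str = "glia"
    marker_logfc_cut: float | None = None  # default per background
    test_fraction: float = 0.25
    importance_sd_mult: float = 2.0
    n_shuffles: int = 1
    n_estimators: int = 100
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.marker_logfc_cut is None:
            self.marker_logfc_cut = MARKER_CUTS.get(self.background, 2.0)


def _dense(X) -> np.ndarray:
    return np.asarray(X.toarray() if sp.issparse(X) else X, dtype=float)


def exclude_subtype_markers(
    adata: ad.AnnData, subtype_col: str = "cluster", cut: float = 3.5
) -> pd.Series:
    """Boolean mask (indexed by gene) of subtype marker genes.

    One-vs-rest log2 fold change per subtype (de-logged group means with
    pseudocount); a gene with logFC above ``cut`` in any subtype is masked
    from classifier training so state models cannot exploit cell identity.
    """
    subtypes = adata.obs[subtype_col].astype(str)
    if subtypes.nunique() < 2:
        raise ValueError("need >= 2 subtypes for marker exclusion")
    X = _dense(adata.X)
    mask = np.zeros(adata.n_vars, dtype=bool)
    for s in subtypes.unique():
        sel = (subtypes == s).to_numpy()
        logfc = group_log2_fc(X[sel], X[~sel])
        mask |= logfc > cut
    return pd.Series(mask, index=adata.var_names, name="is_marker")


def train_state_classifier(
    X: np.ndarray, y: np.ndarray, params: TransferParams
) -> tuple[GradientBoostingClassifier, np.ndarray]:
    """Fit the boosted additive state classifier; returns (model, importances).

    ``y`` must contain both labels.  Importances are the model's per-feature
    global importance scores (non-negative, one per gene).
    """
    labels = np.unique(y)
    if labels.size < 2:
        raise ValueError("training labels must contain both states")
    clf = GradientBoostingClassifier(
        n_estimators=params.n_estimators,
        learning_rate=params.learning_rate,
        max_depth=1,
        random_state=params.seed,
    )
    clf.fit(X, y)
    return clf, clf.feature_importances_


def importance_threshold(importances: np.ndarray, sd_mult: float = 2.0) -> float:
    """Mean + ``sd_mult`` sample standard deviations over all features."""
    imp = np.asarray(importances, dtype=float)
    return float(imp.mean() + sd_mult * imp.std(ddof=1))


def filter_state_genes(
    state_importances: dict[str, pd.Series] | pd.Series,
    identity_importances: pd.Series,
    dea_significant: set[str],
    sd_mult: float = 2.0,
) -> set[str]:
    """Distilled sleep/wake gene list for one background.

    (Union over subtypes of genes above the per-subtype mean + 2 s.d.
    state-importance threshold) minus (genes above the identity classifier's
    own threshold), intersected with the DEA-significant genes.
    """
    if isinstance(state_importances, pd.Series):
        state_importances = {"_": state_importances}
    selected: set[str] = set()
    for imp in state_importances.values():
        thr = importance_threshold(imp.to_numpy(), sd_mult)
        selected |= set(imp.index[imp.to_numpy() > thr])
    id_thr = importance_threshold(identity_importances.to_numpy(), sd_mult)
    identity = set(identity_importances.index[identity_importances.to_numpy() > id_thr])
    return (selected - identity) & set(dea_significant)


class TransferResults:
    """Cross-subtype transfer grids and per-subtype feature importances."""

    def __init__(self, grid: pd.DataFrame, shuffle_grid: pd.DataFrame,
                 state_importances: dict[str, pd.Series],
                 identity_importances: pd.Series,
                 accuracy: pd.Series, params: TransferParams):
        self.grid = grid  # rows: training subtype; columns: evaluation subtype
        self.shuffle_grid = shuffle_grid
        self.state_importances = state_importances
        self.identity_importances = identity_importances
        self.accuracy = accuracy  # held-out same-subtype accuracy
        self.params = params

    def diagonal_margin(self) -> float:
        """min over rows of (diagonal - max off-diagonal)."""
        g = self.grid.to_numpy()
        diag = np.diag(g)
        off = g.copy()
        np.fill_diagonal(off, -np.inf)
        return float((diag - off.max(axis=1)).min())

    def summary(self) -> pd.DataFrame:
        out = self.grid.copy()
        out.index.name = "train_subtype"
        return out.reset_index()

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.grid.to_numpy(), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(self.grid.columns)), self.grid.columns, rotation=90)
        ax.set_yticks(range(len(self.grid.index)), self.grid.index)
        ax.set_xlabel("evaluated on")
        ax.set_ylabel("trained on")
        ax.figure.colorbar(im, ax=ax, label="mean P(true state)")
        return ax


class StateTransfer:
    """Train per-subtype state classifiers and evaluate cross-subtype transfer.

    Parameters
    ----------
    adata : AnnData
        Log-normalized cells of one background, ``cluster`` (subtype) and
        ``condition`` in ``.obs``.
    design : ConditionDesign
        Supplies the sleep/wake grouping of conditions.
    """

    def __init__(self, adata: ad.AnnData, design, params: TransferParams | None = None,
                 marker_mask: pd.Series | None = None):
        self.adata = adata
        self.design = design
        self.params = params or TransferParams()
        self.marker_mask = marker_mask

    def fit(self) -> TransferResults:
        params = self.params
        adata = self.adata
        subtypes = adata.obs["cluster"].astype(str)
        conds = adata.obs["condition"].astype(str)
        state = pd.Series(pd.NA, index=adata.obs_names, dtype=object)
        state[conds.isin(self.design.sleep_conditions).to_numpy()] = "sleep"
        state[conds.isin(self.design.wake_conditions).to_numpy()] = "wake"
        labeled = state.notna().to_numpy()

        mask = self.marker_mask
        if mask is None:
            mask = exclude_subtype_markers(adata[labeled], cut=params.marker_logfc_cut)
        feat = ~mask.reindex(adata.var_names, fill_value=False).to_numpy()
        feat_genes = adata.var_names[feat]
        X = _dense(adata.X)[:, feat]
        y = state.to_numpy()

        names = sorted(subtypes.unique())
        rng = np.random.default_rng(params.seed)
        splits = {}
        for s in names:
            idx = np.flatnonzero((subtypes == s).to_numpy() & labeled)
            train, test = train_test_split(
                idx,
                test_size=params.test_fraction,
                stratify=y[idx],
                random_state=int(rng.integers(2**31)),
            )
            splits[s] = (train, test)

        grid = pd.DataFrame(np.nan, index=names, columns=names)
        shuffle = pd.DataFrame(0.0, index=names, columns=names)
        importances: dict[str, pd.Series] = {}
        accuracy = pd.Series(np.nan, index=names)
        for s in names:
            train, test = splits[s]
            clf, imp = train_state_classifier(X[train], y[train], params)
            importances[s] = pd.Series(imp, index=feat_genes)
            accuracy[s] = float((clf.predict(X[test]) == y[test]).mean())
            for t in names:
                grid.loc[s, t] = _mean_true_prob(clf, X[splits[t][1]], y[splits[t][1]])
            for k in range(params.n_shuffles):
                y_shuf = y.copy()
                y_shuf[train] = rng.permutation(y[train])
                if np.unique(y_shuf[train]).size < 2:  # pathological tiny split
                    continue
                sclf, _ = train_state_classifier(X[train], y_shuf[train], params)
                for t in names:
                    shuffle.loc[s, t] += (
                        _mean_true_prob(sclf, X[splits[t][1]], y[splits[t][1]])
                        / params.n_shuffles
                    )

        # control classifier: predict subtype identity from the same features
        all_train = np.concatenate([splits[s][0] for s in names])
        id_clf, id_imp = train_state_classifier(
            X[all_train], subtypes.to_numpy()[all_train], params
        )
        identity = pd.Series(id_imp, index=feat_genes)

        return TransferResults(grid, shuffle, importances, identity, accuracy, params)


def _mean_true_prob(clf, X: np.ndarray, y_true: np.ndarray) -> float:
    """Mean predicted probability of the true label on held-out cells."""
    proba = clf.predict_proba(X)
    cols = {c: i for i, c in enumerate(clf.classes_)}
    idx = np.array([cols[v] for v in y_true])
    return float(proba[np.arange(len(y_true)), idx].mean())
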