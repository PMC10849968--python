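import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import sleepscreen as ss


def _adata(counts, clusters=None, conditions=None, runs=None, genes=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame({
        "cluster": clusters or ["c0"] * n,
        "condition": conditions or ["ZT8-Sleep"] * n,
        "run": runs or ["run0"] * n,
    }, index=[f"cell{i}" for i in range(n)])
    var = pd.DataFrame(index=genes or [f"g{i}" for i in range(g)])
    return ad.AnnData(X=sp.csr_matrix(counts.astype(float)), obs=obs, var=var)


class TestQcFilter:
    def test_low_gene_cell_removed_with_reason(self):
        counts = np.ones((2, 300))
        counts[0, 150:] = 0  # 150 detected genes
        adata = _adata(counts)
        kept, report = ss.qc_filter(adata, ss.QcParams())
        assert list(kept.obs_names) == ["cell1"]
        assert report.set_index("cell_id").loc["cell0", "reason"] == "min_genes"

    def test_high_mito_cell_removed_by_run_threshold(self):
        genes = [f"mt:{i}" for i in range(5)] + [f"g{i}" for i in range(295)]
        counts = np.ones((2, 300))
        counts[0, :5] = 35  # mito fraction 175/470 ~ 0.37
        adata = _adata(counts, genes=genes)
        params = ss.QcParams(per_run_mito_fraction={"run0": 0.30})
        kept, report = ss.qc_filter(adata, params)
        assert report.set_index("cell_id").loc["cell0", "reason"] == "mito_fraction"
        assert "cell1" in kept.obs_names

    def test_excluded_condition_removed(self):
        counts = np.ones((2, 300))
        adata = _adata(counts, conditions=["ZT2-Wake", "ZT8-Sleep"])
        kept, report = ss.qc_filter(adata, ss.QcParams())
        assert report.set_index("cell_id").loc["cell0", "reason"] == "excluded_condition"
        assert list(kept.obs_names) == ["cell1"]

    def test_all_cells_removed_is_hard_error(self):
        adata = _adata(np.ones((2, 10)))  # 10 genes << 200
        with pytest.raises(ValueError, match="every cell"):
            ss.qc_filter(adata, ss.QcParams())

    def test_idempotent(self):
        design = ss.SyntheticDesign(
            n_clusters=1, cells_per_cluster_condition=10, n_genes=600,
            baseline_mean=1.0, seed=4,
        )
        adata, _, _ = ss.generate_dataset(design)
        once, _ = ss.qc_filter(adata, ss.QcParams())
        twice, report = ss.qc_filter(once, ss.QcParams())
        assert list(twice.obs_names) == list(once.obs_names)
        assert report["kept"].all()


class TestNormalize:
    def test_cell_sums_hit_target_and_cpm_sums_to_million(self):
        adata = _adata(np.random.default_rng(0).poisson(2.0, size=(5, 100)) + 1)
        nd = ss.normalize(adata)
        pre_log = np.expm1(nd.X.toarray())
        assert np.allclose(pre_log.sum(axis=1), 1e4, rtol=1e-6)
        assert np.allclose(np.asarray(nd.layers["cpm"].sum(axis=1)).ravel(), 1e6)

    def test_proportional_cells_normalize_identically(self):
        base = np.array([[1.0, 2.0, 3.0, 4.0]])
        adata = _adata(np.vstack([base, 20 * base]))
        nd = ss.normalize(adata)
        x = nd.X.toarray()
        assert np.allclose(x[0], x[1])

    def test_single_gene_cell(self):
        adata = _adata(np.array([[7.0, 0.0, 0.0]]))
        nd = ss.normalize(adata)
        x = nd.X.toarray()[0]
        assert x[0] == pytest.approx(np.log1p(1e4))
        assert x[1] == x[2] == 0

    def test_zero_total_cell_is_named(self):
        adata = _adata(np.array([[1.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="cell1"):
            ss.normalize(adata)

    def test_commutes_with_cell_subsetting(self):
        adata = _adata(np.random.default_rng(1).poisson(3.0, size=(8, 50)) + 1)
        nd_full = ss.normalize(adata)
        sub = adata[2:6].copy()
        nd_sub = ss.normalize(sub)
        assert np.allclose(nd_full.X.toarray()[2:6], nd_sub.X.toarray())


class TestRunEffectExclusion:
    def test_run_specific_gene_is_masked(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=(120, 30)) + 1
        runs = ["run0"] * 60 + ["run1"] * 60
        counts[:60, 0] += 40  # gene g0 much higher in run0
        adata = ss.normalize(_adata(counts, runs=runs))
        mask = ss.exclude_run_effect_genes(adata, alpha=0.001)
        assert mask["g0"]

    def test_iid_gene_not_masked(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(2.0, size=(120, 30)) + 1
        runs = ["run0"] * 60 + ["run1"] * 60
        adata = ss.normalize(_adata(counts, runs=runs))
        mask = ss.exclude_run_effect_genes(adata, alpha=0.001)
        assert not mask.drop("g0").any()  # g0 included: no effect planted anywhere
        assert not mask["g0"]

    def test_exclude_list_overrides(self):
        counts = np.ones((6, 5))
        adata = ss.normalize(_adata(counts))
        mask = ss.exclude_run_effect_genes(adata, exclude_list={"g3"})
        assert mask["g3"] and mask.sum() == 1

    def test_single_run_masks_only_list(self):
        rng = np.random.default_rng(3)
        adata = ss.normalize(_adata(rng.poisson(2.0, size=(10, 8)) + 1))
        mask = ss.exclude_run_effect_genes(adata, exclude_list={"g1"})
        assert mask["g1"] and mask.sum() == 1


class TestClusterConditionMeans:
    def test_single_cell_conditions_reproduce_values(self):
        counts = np.array([[2.0, 4.0], [6.0, 8.0]])
        adata = ss.normalize(_adata(counts, conditions=["a", "b"]))
        means, n = ss.cluster_condition_means(adata, "c0")
        x = adata.X.toarray()
        assert np.allclose(means["a"], x[0])
        assert np.allclose(means["b"], x[1])
        assert n.to_dict() == {"a": 1, "b": 1}

    def test_empty_condition_is_missing_not_zero(self):
        counts = np.ones((2, 3))
        adata = ss.normalize(_adata(counts, conditions=["a", "a"]))
        means, _ = ss.cluster_condition_means(adata, "c0")
        assert "b" not in means.columns

    def test_constant_gene_gives_constant_row(self):
        counts = np.column_stack([np.full(4, 5.0), np.arange(1.0, 5.0)])
        adata = _adata(counts, conditions=["a", "a", "b", "b"])
        means, _ = ss.cluster_condition_means(adata, "c0")  # raw counts, no norm
        assert means.loc["g0", "a"] == means.loc["g0", "b"] == 5.0

    def test_unknown_cluster_errors(self):
        adata = _adata(np.ones((2, 3)))
        with pytest.raises(KeyError):
            ss.cluster_condition_means(adata, "nope")
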