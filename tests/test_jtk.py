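import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import sleepscreen as ss
from sleepscreen.jtk import (
    ExactKendallNull,
    IneligibleClusterError,
    JtkParams,
    cosine_reference,
    jtk_exact_test,
    kendall_s,
    make_pseudo_replicates,
    prefilter_genes,
)
from conftest import enumerate_jtk_p

ZTS_2REP = np.repeat([2.0, 8.0, 14.0, 20.0], 2)
PARAMS_2REP = JtkParams(n_pseudo_reps=2)


class TestExactNull:
    @pytest.mark.parametrize("sizes", [(2, 2, 2, 2), (1, 2, 2, 3), (3, 3, 2)])
    def test_convolution_matches_enumeration(self, sizes):
        """Exact tail of |S| agrees with brute-force permutation counting."""
        null = ExactKendallNull(sizes)
        # reference: group labels in increasing order
        ref = np.repeat(np.arange(len(sizes), dtype=float), sizes)
        n = ref.size
        perms = np.array(list(itertools.permutations(range(n))))
        values = np.arange(n, dtype=float)
        s_perm = kendall_s(values[perms], ref)
        for s in range(null.max_s + 1):
            expected = float((np.abs(s_perm) >= s).mean())
            assert null.p_two_tailed(s) == pytest.approx(expected, abs=1e-12)

    def test_random_inputs_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            v = rng.normal(size=8)
            res = jtk_exact_test(v, ZTS_2REP, PARAMS_2REP)
            oracle = enumerate_jtk_p(v, ZTS_2REP, PARAMS_2REP.lags)
            assert res["p_exact"][0] == pytest.approx(oracle, abs=1e-12)

    def test_s_bounded_by_tie_structure(self):
        null = ExactKendallNull((2, 2, 2, 2))
        assert null.max_s == 24  # sum over ZT pairs of 2*2
        with pytest.raises(ValueError):
            null.p_two_tailed(25)


class TestJtkExactTest:
    def test_noiseless_reference_reaches_extreme_p(self):
        """Values equal to the lag-0 reference give the maximal S and the
        smallest achievable two-tailed p for the tie structure."""
        ref = np.repeat(cosine_reference([2.0, 8.0, 14.0, 20.0], 0.0), 2)
        res = jtk_exact_test(ref, ZTS_2REP, PARAMS_2REP)
        null = ExactKendallNull((2, 2, 2, 2))
        assert res["S"][0] == null.max_s
        assert res["best_lag"][0] == 0.0
        assert res["p_exact"][0] == pytest.approx(null.p_two_tailed(null.max_s), abs=1e-15)

    def test_constant_gene_gets_p_one(self):
        res = jtk_exact_test(np.ones(8), ZTS_2REP, PARAMS_2REP)
        assert res["p_exact"][0] == 1.0
        assert res["p_adj_lags"][0] == 1.0
        assert res["tau"][0] == 0.0

    def test_antiphase_maps_to_half_period_lag(self):
        ref = np.repeat(cosine_reference([2.0, 8.0, 14.0, 20.0], 0.0), 2)
        in_phase = jtk_exact_test(ref, ZTS_2REP, PARAMS_2REP)
        anti = jtk_exact_test(-ref, ZTS_2REP, PARAMS_2REP)
        assert anti["best_lag"][0] == 12.0
        assert abs(anti["S"][0]) == abs(in_phase["S"][0])
        assert anti["p_exact"][0] == in_phase["p_exact"][0]

    @given(
        scale=hst.floats(min_value=1e-3, max_value=1e3),
        seed=hst.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale, seed):
        """(S, tau, p) are rank statistics: positive scaling changes nothing."""
        v = np.random.default_rng(seed).normal(size=8)
        a = jtk_exact_test(v, ZTS_2REP, PARAMS_2REP)
        b = jtk_exact_test(scale * v, ZTS_2REP, PARAMS_2REP)
        assert a["S"][0] == b["S"][0]
        assert a["tau"][0] == pytest.approx(b["tau"][0])
        assert a["p_exact"][0] == b["p_exact"][0]


@pytest.fixture()
def cluster_data(zt_only_design):
    design = ss.SyntheticDesign(
        n_clusters=1, cells_per_cluster_condition=12, n_genes=40,
        baseline_mean=2.0, design=zt_only_design, seed=21,
    )
    adata, _, _ = ss.generate_dataset(design)
    return ss.normalize(adata)


class TestPseudoReplicates:
    def test_each_cell_used_once_means_preserved(self, cluster_data):
        params = JtkParams(n_pseudo_reps=3)
        reps, rep_zts = make_pseudo_replicates(cluster_data, "c0", params, 5)
        assert reps.shape == (40, 12)
        # weighted mean of rep means equals the ZT mean over all cells
        zt = cluster_data.obs["zt"].to_numpy(dtype=float)
        X = cluster_data.X.toarray()
        for t in params.timepoints:
            cells = zt == t
            sizes = [len(np.array_split(np.arange(cells.sum()), 3)[r]) for r in range(3)]
            cols = np.flatnonzero(rep_zts == t)
            pooled = (reps[:, cols] * np.array(sizes)[None, :]).sum(axis=1) / cells.sum()
            assert np.allclose(pooled, X[cells].mean(axis=0), atol=1e-10)

    def test_three_cells_become_singleton_replicates(self, zt_only_design):
        design = ss.SyntheticDesign(
            n_clusters=1, cells_per_cluster_condition=3, n_genes=10,
            baseline_mean=2.0, design=zt_only_design, seed=2,
        )
        adata, _, _ = ss.generate_dataset(design)
        nd = ss.normalize(adata)
        reps, rep_zts = make_pseudo_replicates(nd, "c0", JtkParams(), 1)
        X = nd.X.toarray()
        zt = nd.obs["zt"].to_numpy(dtype=float)
        for t in (2.0, 8.0, 14.0, 20.0):
            rep_cols = np.sort(reps[:, rep_zts == t], axis=1)
            cells = np.sort(X[zt == t].T, axis=1)
            assert np.allclose(rep_cols, cells)  # a permutation of the cells

    def test_too_few_cells_marks_cluster_ineligible(self, zt_only_design):
        design = ss.SyntheticDesign(
            n_clusters=1, cells_per_cluster_condition=2, n_genes=10,
            baseline_mean=2.0, design=zt_only_design, seed=2,
        )
        adata, _, _ = ss.generate_dataset(design)
        nd = ss.normalize(adata)
        with pytest.raises(IneligibleClusterError):
            make_pseudo_replicates(nd, "c0", JtkParams(n_pseudo_reps=3), 1)

    def test_identical_cells_give_equal_rep_means(self):
        import anndata as ad
        import pandas as pd
        import scipy.sparse as sp

        n = 24
        obs = pd.DataFrame({
            "cluster": ["c0"] * n,
            "condition": ["x"] * n,
            "zt": np.tile(np.repeat([2.0, 8.0, 14.0, 20.0], 6), 1),
        }, index=[f"cell{i}" for i in range(n)])
        X = sp.csr_matrix(np.ones((n, 5)))
        adata = ad.AnnData(X=X, obs=obs)
        reps, _ = make_pseudo_replicates(adata, "c0", JtkParams(), 9)
        assert np.allclose(reps, 1.0)


class TestPrefilter:
    @pytest.mark.parametrize(
        "zt_cpm, expected",
        [
            ((0.9, 0.9, 0.9, 0.9), False),   # flat: fails the fold filter
            ((0.5, 0.75, 0.5, 0.5), False),  # max 0.75 < 0.8: fails expression
            ((2.0, 1.0, 1.0, 1.9), True),    # max 2.0 >= 0.8 and 2.0 >= 1.5-fold
        ],
    )
    def test_expression_and_amplitude_rules(self, zt_cpm, expected):
        mask = prefilter_genes(np.array([zt_cpm]), JtkParams())
        assert mask[0] == expected


class TestConsensus:
    def test_consensus_requires_all_allocations(self, cluster_data):
        """is_cycler holds exactly when the BH-corrected p clears alpha in
        every random allocation, never on a 2-of-3 vote."""
        res = ss.CyclingScreen(cluster_data, JtkParams(seed=3)).fit()
        tab = res.table[res.table.tested]
        cols = [c for c in tab.columns if c.startswith("p_bh_alloc")]
        all_sig = (tab[cols] < res.params.alpha).all(axis=1)
        assert (tab["is_cycler"] == all_sig).all()

    def test_null_cluster_yields_no_consensus_cyclers(self, null_cycling_data):
        nd, _, _ = null_cycling_data
        res = ss.CyclingScreen(nd, JtkParams(seed=17)).fit()
        assert res.n_cyclers["c0"] == 0

    def test_planted_cycler_detected(self, zt_only_design):
        design = ss.SyntheticDesign(
            n_clusters=1, cells_per_cluster_condition=300, n_genes=200,
            n_cyclers_per_cluster=5, cycler_fold=3.0,
            design=zt_only_design, seed=13,
        )
        adata, _, truth = ss.generate_dataset(design)
        nd = ss.normalize(adata)
        res = ss.CyclingScreen(nd, JtkParams(seed=13)).fit()
        assert truth.planted("c0", "cycler") <= res.cyclers("c0")

    def test_ineligible_cluster_flagged(self, zt_only_design):
        design = ss.SyntheticDesign(
            n_clusters=1, cells_per_cluster_condition=2, n_genes=20,
            baseline_mean=2.0, design=zt_only_design, seed=2,
        )
        adata, _, _ = ss.generate_dataset(design)
        nd = ss.normalize(adata)
        res = ss.CyclingScreen(nd, JtkParams()).fit()
        assert "c0" in res.ineligible
        assert res.table.empty
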