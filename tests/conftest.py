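import numpy as np
import pytest

import sleepscreen as ss


@pytest.fixture(scope="session")
def zt_only_design():
    """Four ZT conditions, no sleep/wake split, no drive ranking."""
    return ss.default_design(sleep_wake=False, n_drive=0)


@pytest.fixture(scope="session")
def drive_only_design():
    """Seven drive-ranked conditions d0..d6."""
    return ss.ConditionDesign(
        [ss.Condition(f"d{i}", drive_rank=i) for i in range(7)]
    )


@pytest.fixture(scope="session")
def sleep_wake_design():
    """Minimal two-condition sleep/wake design."""
    return ss.ConditionDesign(
        [ss.Condition("S", sw_group="sleep"), ss.Condition("W", sw_group="wake")]
    )


@pytest.fixture(scope="session")
def null_cycling_data(zt_only_design):
    """Global-null normalized dataset on the circadian sampling grid."""
    design = ss.SyntheticDesign(
        n_clusters=1,
        cells_per_cluster_condition=50,
        n_genes=500,
        design=zt_only_design,
        seed=101,
    )
    adata, cdesign, truth = ss.generate_dataset(design)
    return ss.normalize(adata), cdesign, truth


def enumerate_jtk_p(values: np.ndarray, zts: np.ndarray, lags, period=24.0) -> float:
    """Independent oracle: exhaustive-permutation two-tailed JTK p-value.

    Permutes the observed values over all positions and, per lag, counts
    arrangements whose |Kendall score| meets or exceeds the observed one;
    returns the minimum over lags (pre-Bonferroni).
    """
    from itertools import permutations

    from sleepscreen.jtk import cosine_reference, kendall_s

    values = np.asarray(values, dtype=float)
    perms = np.array(list(permutations(range(values.size))))
    best = 1.0
    for lag in lags:
        ref = np.round(cosine_reference(zts, lag, period), 12)
        s_obs = kendall_s(values, ref)[0]
        s_perm = kendall_s(values[perms], ref)
        best = min(best, float((np.abs(s_perm) >= abs(s_obs)).mean()))
    return best
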