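"""Amplicon aggregation, Mann-Whitney, bootstrapped clustering and PCA."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.special import ndtr, ndtri
from scipy import stats

from methprog.quant import (
    AmpliconTable,
    amplicon_means,
    cluster_support,
    fit_au,
    hcluster,
    mann_whitney,
    pairwise_distances,
    pca,
    tree_clusters,
)


def small_table(values, n_amp=2):
    cols = [f"a{i // (values.shape[1] // n_amp)}.cg{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=cols,
                      index=[f"s{i}" for i in range(values.shape[0])])
    unit_amp = pd.Series({c: c.split(".")[0] for c in cols})
    groups = pd.Series({f"s{i}": "g" for i in range(values.shape[0])})
    return AmpliconTable(df, unit_amp, groups)


class TestAmpliconMeans:
    def test_missing_units_ignored_never_imputed(self):
        t = small_table(np.array([[0.2, 0.4, np.nan, 0.6],
                                  [np.nan, np.nan, 0.5, 0.5]]))
        m = amplicon_means(t)
        assert m.loc["s0", "a0"] == pytest.approx(0.3)
        assert np.isnan(m.loc["s1", "a0"])
        assert m.loc["s1", "a1"] == pytest.approx(0.5)

    def test_matches_hand_computation_on_random_fixture(self, rng):
        vals = rng.random((6, 8))
        t = small_table(vals)
        m = amplicon_means(t)
        for i in range(6):
            assert m.iloc[i, 0] == pytest.approx(vals[i, :4].mean(), abs=1e-12)
            assert m.iloc[i, 1] == pytest.approx(vals[i, 4:].mean(), abs=1e-12)

    def test_invariant_to_unit_ordering(self, rng):
        vals = rng.random((4, 8))
        t = small_table(vals)
        perm = list(rng.permutation(t.values.columns))
        t2 = AmpliconTable(t.values[perm], t.unit_amplicon, t.sample_group)
        assert np.allclose(amplicon_means(t).values, amplicon_means(t2).values)

    def test_rejects_out_of_range_fractions(self):
        with pytest.raises(ValueError):
            small_table(np.array([[0.2, 1.4, 0.1, 0.3]]))


class TestMannWhitney:
    def test_exact_enumeration_of_separated_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3) labelings as extreme

    def test_symmetric_in_arguments_and_u_complement(self, rng):
        a, b = rng.random(6), rng.random(7)
        ua, pa = mann_whitney(a, b)
        ub, pb = mann_whitney(b, a)
        assert pa == pytest.approx(pb)
        assert ua + ub == len(a) * len(b)  # no ties

    def test_identical_groups_not_significant(self):
        _, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.85

    @pytest.mark.parametrize("seed", range(50))
    def test_normal_approximation_close_to_exact_at_n7(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 7), rng.normal(0.5, 1, 7)
        _, p_exact = mann_whitney(a, b, exact_max=8)
        _, p_approx = mann_whitney(a, b, exact_max=0)  # force approximation
        assert abs(p_exact - p_approx) < 0.02

    def test_empty_or_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


def brute_force_average_linkage(d):
    """O(n^3) agglomerative average linkage from a distance matrix."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    merges = []
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        mi, mj = active.pop(i), active.pop(j)
        merged = mi + mj
        new_d = {}
        for k, mk in active.items():
            num = sum(d[a, b] for a in merged for b in mk)
            new_d[k] = num / (len(merged) * len(mk))
        dist = {
            (a, b): v for (a, b), v in dist.items() if {a, b} <= set(active)
        }
        for k, v in new_d.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        active[next_id] = merged
        merges.append((sorted((i, j)), h, len(merged)))
        next_id += 1
    return merges


class TestHcluster:
    def test_two_samples_single_merge_at_their_distance(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        z = hcluster(x)
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(5.0)

    def test_collinear_points_merge_nearest_pair_first(self):
        x = np.array([[0.0], [1.0], [10.0]])
        z = hcluster(x)
        assert set(z[0, :2].astype(int)) == {0, 1}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((20, 5))
        z = hcluster(x)
        d = pairwise_distances(x)
        expected = brute_force_average_linkage(d)
        for row, (pair, height, size) in zip(z, expected):
            assert sorted(row[:2].astype(int)) == pair
            assert row[2] == pytest.approx(height)
            assert int(row[3]) == size

    def test_missing_features_pairwise_deleted_with_rescaling(self):
        x = np.array([[1.0, np.nan, 3.0], [1.0, 5.0, 6.0]])
        d = pairwise_distances(x)
        assert d[0, 1] == pytest.approx(np.sqrt(9.0 * 3 / 2))

    def test_no_shared_features_rejected(self):
        x = np.array([[1.0, np.nan], [np.nan, 2.0]])
        with pytest.raises(ValueError):
            hcluster(x)


def two_group_fixture(seed=42, gap=10.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (10, 50))
    x[5:] += gap
    return x


class TestClusterSupport:
    def test_clean_split_has_high_bp_and_au(self):
        cs = cluster_support(two_group_fixture(), B=200, seed=7)
        idx = {node: i for i, node in enumerate(cs.nodes)}
        for group in (frozenset(range(5)), frozenset(range(5, 10))):
            i = idx[group]
            assert cs.bp[i] >= 0.95
            assert cs.au[i] >= 0.95

    def test_saturated_node_flagged_and_reported_one(self):
        cs = cluster_support(two_group_fixture(), B=150, seed=1)
        idx = {node: i for i, node in enumerate(cs.nodes)}
        i = idx[frozenset(range(5))]
        if cs.flags[i] == "saturated":
            assert cs.au[i] == 1.0

    def test_au_reproduces_weighted_least_squares_fit(self):
        scales = np.linspace(0.5, 1.4, 10)
        bp_row = np.array([0.62, 0.68, 0.74, 0.78, 0.83, 0.85, 0.88, 0.90, 0.92, 0.93])
        au, flag = fit_au(bp_row, scales, B=1000)
        z = ndtri(1 - bp_row)
        w = (1000 * stats.norm.pdf(z) ** 2) / (bp_row * (1 - bp_row))
        design = np.column_stack([np.sqrt(scales), 1 / np.sqrt(scales)])
        coef, *_ = np.linalg.lstsq(design * np.sqrt(w)[:, None], z * np.sqrt(w), rcond=None)
        assert flag == ""
        assert au == pytest.approx(1 - ndtr(coef[0] - coef[1]), abs=1e-8)

    def test_two_seeded_runs_agree_within_bootstrap_noise(self):
        x = two_group_fixture()
        a = cluster_support(x, B=1000, seed=3)
        b = cluster_support(x, B=1000, seed=4)
        assert a.node_labels() == b.node_labels()
        assert np.abs(a.bp - b.bp).max() < 0.06

    def test_tree_clusters_enumerates_internal_nodes(self):
        x = two_group_fixture()
        z = hcluster(x)
        nodes = tree_clusters(z, 10)
        assert len(nodes) == 9
        assert nodes[-1] == frozenset(range(10))


class TestPca:
    def test_identical_samples_zero_variance(self):
        res = pca(np.ones((5, 8)))
        assert np.allclose(res.explained_variance_ratio, 0.0)

    def test_two_groups_separate_on_pc1(self):
        res = pca(two_group_fixture(seed=8, gap=6.0))
        pc1 = res.scores["PC1"].values
        assert res.explained_variance_ratio[0] > res.explained_variance_ratio[1:].max()
        lo, hi = pc1[:5], pc1[5:]
        assert max(lo.max(), hi.max()) - min(lo.min(), hi.min()) > 0  # sanity
        assert (lo.max() < hi.min()) or (hi.max() < lo.min())  # margin between groups

    def test_variance_fractions_sum_to_one_full_rank(self, rng):
        x = rng.normal(0, 1, (6, 4))
        res = pca(x)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_orthogonal(self, rng):
        x = rng.normal(0, 1, (8, 20))
        s = pca(x).scores.values
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_missing_values_rejected(self):
        x = np.ones((3, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            pca(x)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=2, max_size=8, unique=True),
       st.lists(st.floats(-50, 50), min_size=2, max_size=8, unique=True))
def test_mann_whitney_symmetry_and_complement_hold_generally(a, b):
    """p(a,b) = p(b,a) and U_a + U_b = n_a * n_b whenever there are no ties."""
    if set(a) & set(b):
        return
    ua, pa = mann_whitney(a, b)
    ub, pb = mann_whitney(b, a)
    assert pa == pytest.approx(pb, rel=1e-9)
    assert ua + ub == pytest.approx(len(a) * len(b))
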