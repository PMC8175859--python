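"""Normalization, GFS combination, differential ranking and CCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfsnet.local_features import FeatureVector
from gfsnet.scoring import (
    GFSWeights,
    compute_feature_table,
    differential_ranking,
    first_canonical_correlation,
    fit_gfs_weights,
    gfs,
    normalize_minmax,
    rank_group_difference,
)
from gfsnet.twohop_rwr import WalkConfig

from conftest import make_graph, random_graph
from oracles import brute_first_cca


def fv(values, name="f"):
    labels = tuple(f"R{i + 1}" for i in range(len(values)))
    return FeatureVector(name, labels, np.asarray(values, dtype=float))


class TestNormalizeMinmax:
    def test_affine_rescale(self):
        np.testing.assert_allclose(
            normalize_minmax(fv([2, 4, 6])).values, [0, 0.5, 1]
        )

    def test_constant_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_minmax(fv([5, 5, 5]))
        np.testing.assert_array_equal(out.values, [0, 0, 0])

    def test_idempotent_once_normalized(self):
        once = normalize_minmax(fv([3, 9, 7]))
        twice = normalize_minmax(fv(once.values))
        np.testing.assert_allclose(once.values, twice.values, atol=1e-15)


class TestFeatureTableAndGFS:
    def test_symmetric_triangle_all_normalized_zero(self):
        k3 = make_graph(np.ones((3, 3)) - np.eye(3))
        table = compute_feature_table(k3, WalkConfig(c=0.85))
        np.testing.assert_array_equal(table.normalized_matrix, np.zeros((3, 5)))
        np.testing.assert_array_equal(gfs(table).values, [0, 0, 0])

    def test_path3_degree_column(self, path3):
        table = compute_feature_table(path3)
        np.testing.assert_allclose(table.normalized[0].values, [0, 1, 0])

    def test_gfs_degenerate_and_equal_weights(self, path3):
        table = compute_feature_table(path3)
        only_degree = gfs(table, GFSWeights(np.array([1.0, 0, 0, 0, 0])))
        np.testing.assert_allclose(only_degree.values, table.normalized[0].values)
        # the star hub maximizes all four classical features, so a convex
        # combination restricted to them gives the hub GFS = 1 (the 2-hop
        # score is excluded: leaves trade mass among themselves via the
        # 2-step operator, so the hub need not maximize S_2hop)
        W = np.zeros((5, 5))
        W[0, 1:] = 1.0
        t = compute_feature_table(make_graph(W + W.T))
        classical = GFSWeights(np.array([0.25, 0.25, 0.25, 0.25, 0.0]))
        assert gfs(t, classical).values[0] == pytest.approx(1.0)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            GFSWeights(np.array([1, 1, 1, 1, 1.0]))
        with pytest.raises(ValueError, match="nonnegative"):
            GFSWeights(np.array([-0.2, 0.3, 0.3, 0.3, 0.3]))
        with pytest.raises(ValueError, match="5 weights"):
            GFSWeights(np.array([0.5, 0.5]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_gfs_monotone_in_each_feature(self, seed):
        """Raising one normalized feature never lowers a node's GFS."""
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 8, connected=True)
        table = compute_feature_table(g)
        w = GFSWeights.equal()
        base = gfs(table, w).values
        M = table.normalized_matrix
        j = seed % 5
        i = seed % 8
        bumped = M.copy()
        bumped[i, j] += 0.25
        assert float(bumped[i] @ w.w) >= base[i]


class TestFitWeights:
    def _table(self, rng, n=12):
        g = random_graph(rng, n, connected=True)
        return compute_feature_table(g)

    def test_perfect_single_feature_fit(self, rng):
        table = self._table(rng)
        w = fit_gfs_weights(table, table.normalized[0].values)
        assert w.w[0] == pytest.approx(1.0, abs=1e-8)

    def test_two_feature_mixture_recovered(self, rng):
        table = self._table(rng, n=20)
        target = 0.5 * table.normalized[0].values + 0.5 * table.normalized[2].values
        w = fit_gfs_weights(table, target)
        assert w.w[0] + w.w[2] == pytest.approx(1.0, abs=1e-6)
        assert w.w[1] + w.w[3] + w.w[4] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_observations(self, rng):
        g = random_graph(rng, 4, connected=True)
        table = compute_feature_table(g)
        with pytest.raises(ValueError, match="at least 6"):
            fit_gfs_weights(table, np.ones(4))

    def test_uncorrelated_scores_no_crash_weights_valid(self, rng):
        table = self._table(rng, n=40)
        w = fit_gfs_weights(table, rng.standard_normal(40))
        assert w.w.sum() == pytest.approx(1.0)


class TestDifferentialRanking:
    def test_identical_groups_zero_delta_label_order(self):
        a = fv([0.3, 0.2, 0.9], "GFS")
        r = differential_ranking(a, a)
        np.testing.assert_array_equal(r.delta, [0, 0, 0])
        assert [r.labels[i] for i in r.order] == ["R1", "R2", "R3"]

    def test_rank_by_descending_delta(self):
        r = differential_ranking(fv([0.1, 0.5, 0.3]), fv([0.0, 0.0, 0.0]))
        np.testing.assert_array_equal(r.rank, [3, 1, 2])
        assert r.top(2) == [("R2", 0.5), ("R3", 0.3)]

    def test_antisymmetry(self, rng):
        a, b = fv(rng.random(9)), fv(rng.random(9))
        fwd = differential_ranking(a, b)
        rev = differential_ranking(b, a)
        np.testing.assert_allclose(fwd.delta, -rev.delta, atol=1e-15)
        np.testing.assert_array_equal(fwd.order, rev.order[::-1])

    def test_label_mismatch_and_bad_k(self):
        a = fv([1.0, 2.0])
        b = FeatureVector("GFS", ("x", "y"), np.zeros(2))
        with pytest.raises(ValueError, match="labels"):
            differential_ranking(a, b)
        with pytest.raises(ValueError, match="top-k"):
            differential_ranking(a, fv([0.0, 0.0])).top(5)

    def test_end_to_end_determinism(self, rng):
        g1 = random_graph(rng, 12, connected=True)
        g2 = random_graph(rng, 12, connected=True)
        r1, *_ = rank_group_difference(g1, g2)
        r2, *_ = rank_group_difference(g1, g2)
        np.testing.assert_array_equal(r1.delta, r2.delta)
        np.testing.assert_array_equal(r1.order, r2.order)


class TestCCA:
    def test_perfect_linear_relation(self, rng):
        x = rng.standard_normal((30, 1))
        res = first_canonical_correlation(x, 2 * x + 7)
        assert res.rho == pytest.approx(1.0, abs=1e-10)

    def test_single_pair_reduces_to_pearson(self):
        x = np.array([[1.0], [2.0], [4.0]])
        y = np.array([[2.0], [1.0], [3.0]])
        r = np.corrcoef(x.ravel(), y.ravel())[0, 1]
        res = first_canonical_correlation(x, y)
        assert res.rho == pytest.approx(abs(r), abs=1e-12)

    def test_matches_brute_force_maximizer(self, rng):
        X = rng.standard_normal((200, 2))
        Y = 0.4 * X @ rng.standard_normal((2, 2)) + rng.standard_normal((200, 2))
        res = first_canonical_correlation(X, Y)
        assert res.rho == pytest.approx(brute_first_cca(X, Y), abs=1e-6)

    def test_affine_invariance(self, rng):
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 2))
        rho0 = first_canonical_correlation(X, Y).rho
        Tx = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        Ty = rng.standard_normal((2, 2)) + 3 * np.eye(2)
        rho1 = first_canonical_correlation(X @ Tx + 5, Y @ Ty - 2).rho
        assert rho1 == pytest.approx(rho0, abs=1e-8)

    def test_composites_have_unit_variance(self, rng):
        X = rng.standard_normal((40, 2))
        Y = rng.standard_normal((40, 3))
        res = first_canonical_correlation(X, Y)
        u = (X - X.mean(0)) @ res.x_loadings
        v = (Y - Y.mean(0)) @ res.y_loadings
        assert u.var(ddof=1) == pytest.approx(1.0, abs=1e-8)
        assert v.var(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_errors_and_constant_column_drop(self, rng):
        with pytest.raises(ValueError, match="3 observations"):
            first_canonical_correlation(np.zeros((2, 1)), np.zeros((2, 1)))
        with pytest.raises(ValueError, match="observation counts"):
            first_canonical_correlation(np.zeros((5, 1)), np.zeros((4, 1)))
        X = rng.standard_normal((20, 2))
        X[:, 1] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = first_canonical_correlation(X, rng.standard_normal((20, 1)))
        assert res.x_columns == ("x1",)
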