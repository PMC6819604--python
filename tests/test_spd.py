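"""Progression discovery: MSTs, permutation fit tests, block selection, ordering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spdm import spd
from spdm.feature_table import GroupProfiles, normalize_features


def profiles_from_values(values: np.ndarray, feature_ids=None) -> GroupProfiles:
    """GroupProfiles with groups 1..G from a raw G x p value matrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    G, p = values.shape
    ids = feature_ids or [f"f{j}" for j in range(p)]
    means = pd.DataFrame(values, index=range(1, G + 1), columns=ids)
    prof = GroupProfiles(means=means, n_samples=pd.Series([1] * G, index=means.index))
    return normalize_features(prof)


def enumerate_spanning_trees(G: int):
    """All spanning trees of the complete graph on nodes 1..G (small G only)."""
    nodes = list(range(1, G + 1))
    all_edges = list(itertools.combinations(nodes, 2))
    for subset in itertools.combinations(all_edges, G - 1):
        # connectivity check via union-find
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            yield subset


class TestBuildMST:
    def test_single_feature_is_sorted_path(self):
        prof = profiles_from_values([0.1, 0.5, 0.2])
        tree = spd.build_mst(prof, ["f0"])
        assert {(u, v) for u, v, _ in tree.edges} == {(1, 3), (2, 3)}

    def test_all_equal_values_tie_break_is_consecutive_path(self):
        prof = profiles_from_values([0.3] * 6)
        tree = spd.build_mst(prof, ["f0"])
        assert {(u, v) for u, v, _ in tree.edges} == {(i, i + 1) for i in range(1, 6)}

    @pytest.mark.parametrize("g", [4, 5])
    def test_matches_exhaustive_minimum(self, g):
        rng = np.random.default_rng(42)
        for _ in range(5):
            vals = rng.normal(size=(g, 2))
            prof = profiles_from_values(vals)
            tree = spd.build_mst(prof, prof.feature_ids)
            Z = prof.normalized.to_numpy()

            def weight(edge_set):
                return sum(
                    np.linalg.norm(Z[u - 1] - Z[v - 1]) for u, v in edge_set
                )

            best = min(weight(t) for t in enumerate_spanning_trees(g))
            assert tree.total_weight() == pytest.approx(best)

    def test_matches_scipy_mst_weight_at_g14(self):
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(7)
        vals = rng.normal(size=(14, 3))
        prof = profiles_from_values(vals)
        tree = spd.build_mst(prof, prof.feature_ids)
        D = squareform(pdist(prof.normalized.to_numpy()))
        ref = minimum_spanning_tree(D).sum()
        assert tree.total_weight() == pytest.approx(float(ref))

    def test_unknown_feature_raises(self):
        prof = profiles_from_values([1.0, 2.0])
        with pytest.raises(KeyError):
            spd.build_mst(prof, ["nope"])


class TestTreeCost:
    def test_path_cost(self):
        tree = spd.FeatureMST((1, 2, 3), ((1, 2, 1.0), (2, 3, 1.0)), ("f",))
        assert spd.tree_cost({1: 1, 2: 2, 3: 3}, tree) == 2

    def test_own_mst_cost_is_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.normal(size=10)
            prof = profiles_from_values(vals)
            tree = spd.build_mst(prof, ["f0"])
            z = prof.normalized["f0"]
            assert spd.tree_cost(z, tree) == pytest.approx(z.max() - z.min())

    def test_constant_values_zero_cost(self):
        tree = spd.FeatureMST((1, 2, 3), ((1, 2, 0.0), (1, 3, 0.0)), ("f",))
        assert spd.tree_cost({1: 5, 2: 5, 3: 5}, tree) == 0

    def test_missing_node_value(self):
        tree = spd.FeatureMST((1, 2), ((1, 2, 1.0),), ("f",))
        with pytest.raises(KeyError):
            spd.tree_cost({1: 0.0}, tree)


class TestFitPvalue:
    def test_constant_feature_p_one(self):
        tree = spd.FeatureMST((1, 2, 3, 4), tuple((i, i + 1, 0.1) for i in (1, 2, 3)), ("f",))
        assert spd.fit_pvalue({n: 2.0 for n in tree.nodes}, tree, n_perm=500, rng_seed=1) == 1.0

    def test_exhaustive_enumeration_g3(self):
        # values 1,2,3 on path 1-2-3: permutation costs are {2,2,3,3,4,4};
        # observed cost 2 is tied by its reversal -> p = (1+2)/(1+6)
        tree = spd.FeatureMST((1, 2, 3), ((1, 2, 1.0), (2, 3, 1.0)), ("f",))
        p = spd.fit_pvalue_exhaustive({1: 1.0, 2: 2.0, 3: 3.0}, tree)
        assert p == pytest.approx(3 / 7)

    @pytest.mark.parametrize("g", [4, 5])
    def test_exhaustive_matches_independent_enumeration(self, g):
        rng = np.random.default_rng(g)
        vals = {n: float(v) for n, v in zip(range(1, g + 1), rng.normal(size=g))}
        prof = profiles_from_values([vals[n] for n in sorted(vals)])
        tree = spd.build_mst(prof, ["f0"])
        obs = spd.tree_cost(vals, tree)
        count = sum(
            1
            for perm in itertools.permutations(sorted(vals))
            for cost in [
                sum(abs(vals[perm[u - 1]] - vals[perm[v - 1]]) for u, v, _ in tree.edges)
            ]
            if cost <= obs * (1 + 1e-9) + 1e-12
        )
        import math

        expected = (1 + count) / (1 + math.factorial(g))
        assert spd.fit_pvalue_exhaustive(vals, tree) == pytest.approx(expected)

    def test_own_tree_of_distinct_values_is_significant_at_g14(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=14)
        prof = profiles_from_values(vals)
        tree = spd.build_mst(prof, ["f0"])
        p = spd.fit_pvalue(prof.normalized["f0"], tree, n_perm=1000, rng_seed=5)
        assert p <= 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=8)
        prof_z = profiles_from_values(vals)
        tree = spd.build_mst(prof_z, ["f0"])
        z = prof_z.normalized["f0"]
        mm = (z - z.min()) / (z.max() - z.min())
        p_z = spd.fit_pvalue(z, tree, n_perm=400, rng_seed=3)
        p_mm = spd.fit_pvalue(mm, tree, n_perm=400, rng_seed=3)
        assert p_z == p_mm


class TestFitMatrixAndSimilarity:
    def test_identical_features_identical_rows(self):
        vals = np.array([[0.1, 0.1, 0.3], [0.2, 0.2, 0.5], [0.5, 0.5, 0.1], [0.9, 0.9, 0.2]])
        prof = profiles_from_values(vals, ["a", "a2", "b"])
        trees = [spd.build_mst(prof, [f]) for f in prof.feature_ids]
        fit = spd.fit_matrix(prof, trees, n_perm=200, seed=4)
        assert (fit.pvalues.loc["a"] == fit.pvalues.loc["a2"]).all()

    def test_determinism_and_threshold(self):
        rng = np.random.default_rng(2)
        prof = profiles_from_values(rng.normal(size=(6, 4)))
        trees = [spd.build_mst(prof, [f]) for f in prof.feature_ids]
        fit1 = spd.fit_matrix(prof, trees, n_perm=300, seed=11)
        fit2 = spd.fit_matrix(prof, trees, n_perm=300, seed=11)
        pd.testing.assert_frame_equal(fit1.pvalues, fit2.pvalues)
        assert (fit1.fits == (fit1.pvalues <= fit1.alpha)).all().all()

    def test_similarity_counts_shared_trees(self):
        pv = pd.DataFrame(
            [[0.01, 0.01, 0.9], [0.01, 0.01, 0.9], [0.9, 0.9, 0.01]],
            index=list("abc"),
            columns=range(3),
        )
        fit = spd.FitMatrix(pvalues=pv, alpha=0.05, n_perm=100, seed=0)
        S = spd.similarity_matrix(fit)
        assert S.loc["a", "b"] == 2
        assert S.loc["a", "c"] == 0
        assert S.loc["a", "a"] == 2

    def test_similarity_invariants_on_random_fits(self):
        rng = np.random.default_rng(8)
        pv = pd.DataFrame(
            rng.uniform(size=(12, 20)), index=[f"f{i}" for i in range(12)], columns=range(20)
        )
        S = spd.similarity_matrix(spd.FitMatrix(pv, alpha=0.3, n_perm=10, seed=0))
        Sv = S.to_numpy()
        assert (Sv == Sv.T).all()
        diag = np.diag(Sv)
        assert (Sv <= np.minimum.outer(diag, diag)).all()


class TestSelection:
    def _block_similarity(self):
        rng = np.random.default_rng(1)
        n = 50
        ids = [f"f{i:02d}" for i in range(n)]
        S = np.zeros((n, n), dtype=int)
        S[:10, :10] = 20
        np.fill_diagonal(S, 25)
        return pd.DataFrame(S, index=ids, columns=ids)

    def test_auto_finds_dense_block(self):
        S = self._block_similarity()
        sel = spd.select_progression_features(S, method="auto")
        assert set(sel) == set(S.index[:10])

    def test_manual_returns_requested(self):
        S = self._block_similarity()
        assert spd.select_progression_features(
            S, method="manual", manual_ids=["f00", "f03"]
        ) == ("f00", "f03")

    def test_all_zero_similarity_warns_and_returns_empty(self):
        S = pd.DataFrame(np.zeros((8, 8), dtype=int), index=list("abcdefgh"), columns=list("abcdefgh"))
        with pytest.warns(UserWarning, match="no coherent block"):
            assert spd.select_progression_features(S, method="auto") == ()

    def test_too_few_features_for_auto(self):
        S = pd.DataFrame(np.ones((3, 3), dtype=int), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            spd.select_progression_features(S, method="auto")


class TestOverallMSTAndOrdering:
    def test_single_feature_selection_equals_its_own_tree(self):
        rng = np.random.default_rng(14)
        prof = profiles_from_values(rng.normal(size=(7, 3)))
        own = spd.build_mst(prof, ["f1"])
        joint = spd.overall_mst(prof, ["f1"])
        assert {(u, v) for u, v, _ in joint.edges} == {(u, v) for u, v, _ in own.edges}

    def test_two_monotone_features_give_path_in_group_order(self):
        g = 6
        t = np.linspace(0, 1, g)
        prof = profiles_from_values(np.column_stack([t, 2 * t]))
        tree = spd.overall_mst(prof, prof.feature_ids)
        assert {(u, v) for u, v, _ in tree.edges} == {(i, i + 1) for i in range(1, g)}
        res = spd.extract_ordering(tree)
        assert res.ordering == tuple(range(1, g + 1))

    def test_empty_selection_rejected(self):
        prof = profiles_from_values([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            spd.overall_mst(prof, [])

    def test_diameter_of_path_is_itself(self):
        tree = spd.FeatureMST((1, 2, 3), ((1, 3, 1.0), (1, 2, 1.0)), ("f",))
        res = spd.extract_ordering(tree)  # path graph 3-1-2
        assert res.ordering in ((3, 1, 2), (2, 1, 3))
        assert res.off_path == {}

    def test_star_has_one_off_path_node(self):
        tree = spd.FeatureMST(
            (1, 2, 3, 4), ((1, 2, 1.0), (1, 3, 1.0), (1, 4, 1.0)), ("f",)
        )
        res = spd.extract_ordering(tree)
        assert len(res.ordering) == 3
        assert list(res.off_path.values()) == [1]  # attached at the hub

    def test_single_node_tree(self):
        tree = spd.FeatureMST((1,), (), ("f",))
        assert spd.extract_ordering(tree).ordering == (1,)

    def test_weighted_diameter(self):
        # hop diameter prefers 2-1-3; long weighted spur 1-4 wins under weights
        tree = spd.FeatureMST(
            (1, 2, 3, 4), ((1, 2, 1.0), (1, 3, 1.0), (1, 4, 10.0)), ("f",)
        )
        res = spd.extract_ordering(tree, weighted=True)
        assert 4 in res.ordering


class TestCompareOrderings:
    def test_identity_and_reversal(self):
        truth = [1, 2, 3, 4, 5]
        assert spd.compare_orderings(truth, truth) == 1.0
        assert spd.compare_orderings(truth[::-1], truth) == 1.0

    def test_partial_swap(self):
        assert spd.compare_orderings([1, 3, 2, 4], [1, 2, 3, 4]) == pytest.approx(0.8)

    def test_subset_scored_on_common_elements(self):
        assert spd.compare_orderings([2, 3, 4], [1, 2, 3, 4, 5]) == 1.0

    def test_too_few_common_elements(self):
        with pytest.raises(ValueError):
            spd.compare_orderings([1, 2], [1, 2, 3])


class TestFixtureTrees:
    def test_increasing_feature_mst_is_group_path(self, fixture_profiles):
        tree = spd.build_mst(fixture_profiles, ["inc"])
        assert {(u, v) for u, v, _ in tree.edges} == {(i, i + 1) for i in range(1, 5)}

    def test_background_features_fit_no_tree(self, fixture_profiles):
        trees = [spd.build_mst(fixture_profiles, [f]) for f in fixture_profiles.feature_ids]
        fit = spd.fit_matrix(fixture_profiles, trees, alpha=0.05, n_perm=1000, seed=7)
        for bg in ("bg1", "bg2"):
            assert not fit.fits.loc[bg].any()
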