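import numpy as np
import pytest

from cnnbrf.brf import (
    BRFConfig,
    BRFModel,
    TreeNode,
    choose_split,
    fit,
    grow_tree,
    predict_proba,
    select_candidate_features,
    split_structural_estimation,
)
from cnnbrf.exceptions import ConfigurationError

from _oracles import reference_tree, tree_to_tuple, trees_equal


class TestStructuralEstimationSplit:
    def test_even_split_is_disjoint_cover(self):
        rng = np.random.default_rng(0)
        s, e = split_structural_estimation(np.arange(10), 0.5, rng)
        assert len(s) == 5 and len(e) == 5
        assert sorted(np.concatenate([s, e])) == list(range(10))

    def test_odd_count_rounds_half_up(self):
        rng = np.random.default_rng(0)
        s, e = split_structural_estimation(np.arange(11), 0.5, rng)
        assert (len(s), len(e)) == (6, 5)

    def test_seeded_partition_reproducible(self):
        a = split_structural_estimation(np.arange(20), 0.5, np.random.default_rng(7))
        b = split_structural_estimation(np.arange(20), 0.5, np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            split_structural_estimation(np.arange(1), 0.5, np.random.default_rng(0))


class TestCandidateFeatures:
    def test_single_feature_universe(self):
        for seed in range(5):
            out = select_candidate_features(1, 0.5, np.random.default_rng(seed))
            assert list(out) == [0]

    def test_subset_size_is_ceil_sqrt(self):
        out = select_candidate_features(100, 0.0, np.random.default_rng(0))
        assert len(out) == 10 and len(set(out)) == 10

    def test_single_branch_size_one(self):
        out = select_candidate_features(100, 1.0, np.random.default_rng(0))
        assert len(out) == 1

    def test_b1_empirical_frequency_within_3_sigma(self):
        p1, n = 0.3, 10_000
        rng = np.random.default_rng(123)
        singles = sum(
            len(select_candidate_features(100, p1, rng)) == 1 for _ in range(n)
        )
        sigma = np.sqrt(p1 * (1 - p1) / n)
        assert abs(singles / n - p1) < 3 * sigma + 1e-12


class TestChooseSplit:
    def test_two_point_node_gini_split(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        f, thr = choose_split(X, y, np.array([0]), p2=0.0, rng=np.random.default_rng(0))
        assert f == 0 and thr == pytest.approx(0.5)

    def test_constant_candidates_return_none(self):
        X = np.ones((4, 2))
        y = np.array([0, 1, 0, 1])
        assert choose_split(X, y, np.array([0, 1]), 0.0, np.random.default_rng(0)) is None

    def test_random_branch_threshold_within_value_range(self):
        X = np.array([[0.2], [0.8], [0.5]])
        y = np.array([0, 1, 0])
        for seed in range(10):
            f, thr = choose_split(
                X, y, np.array([0]), p2=1.0, rng=np.random.default_rng(seed)
            )
            assert 0.2 < thr < 0.8

    def test_gini_tie_breaks_to_lowest_feature_index(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        X = np.column_stack([x, x])  # identical columns -> tied impurity
        y = np.array([0, 0, 1, 1])
        f, _ = choose_split(X, y, np.array([1, 0]), 0.0, np.random.default_rng(0))
        assert f == 0

    def test_b2_empirical_frequency_within_3_sigma(self):
        # with 2 samples the impurity branch always answers 0.5;
        # the random branch answers uniform(0,1) != 0.5 almost surely
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        p2, n = 0.3, 10_000
        rng = np.random.default_rng(99)
        randoms = sum(
            choose_split(X, y, np.array([0]), p2, rng)[1] != 0.5 for _ in range(n)
        )
        sigma = np.sqrt(p2 * (1 - p2) / n)
        assert abs(randoms / n - p2) < 3 * sigma + 1e-12

    def test_exhaustive_search_matches_bruteforce_on_random_nodes(self):
        # oracle: plain python enumeration of candidates x midpoints
        def brute(X, y, candidates):
            best = None
            for f in sorted(candidates):
                xs = sorted(set(X[:, f]))
                for a, b in zip(xs[:-1], xs[1:]):
                    thr = (a + b) / 2
                    left = y[X[:, f] <= thr]
                    right = y[X[:, f] > thr]
                    g = sum(
                        len(part) * (1 - (part.mean()) ** 2 - (1 - part.mean()) ** 2)
                        for part in (left, right)
                    ) / len(y)
                    if best is None or g < best[0] - 1e-12:
                        best = (g, f, thr)
            return None if best is None else (best[1], best[2])

        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, (25, 4)).round(2)
            y = rng.integers(0, 2, 25)
            if y.min() == y.max():
                continue
            cands = np.array([0, 1, 2, 3])
            got = choose_split(X, y, cands, 0.0, np.random.default_rng(0))
            assert got == brute(X, y, cands)


class TestGrowTree:
    CFG = BRFConfig(n_trees=1, p1=0.0, p2=0.0, min_split=2, bootstrap=False)

    def test_pure_structural_node_is_leaf(self):
        X = np.random.default_rng(0).uniform(0, 1, (8, 3))
        y = np.ones(8, dtype=int)
        t = grow_tree(X, y, X, y, self.CFG, np.random.default_rng(0))
        assert t.is_leaf and t.positive_fraction == 1.0

    def test_separable_one_feature_gives_depth_one_pure_leaves(self):
        X = np.array([[0.1], [0.2], [0.3], [0.7], [0.8], [0.9]])
        y = np.array([0, 0, 0, 1, 1, 1])
        t = grow_tree(X, y, X, y, self.CFG, np.random.default_rng(0))
        assert not t.is_leaf and t.depth() == 1
        assert {t.left.positive_fraction, t.right.positive_fraction} == {0.0, 1.0}

    def test_max_depth_zero_gives_root_leaf_with_global_fraction(self):
        cfg = BRFConfig(n_trees=1, p1=0, p2=0, max_depth=0, bootstrap=False)
        X = np.array([[0.0], [1.0], [0.5]])
        ys = np.array([0, 1, 1])
        t = grow_tree(X, ys, X, ys, cfg, np.random.default_rng(0))
        assert t.is_leaf and t.positive_fraction == pytest.approx(2 / 3)

    def test_empty_structural_set_rejected(self):
        with pytest.raises(ConfigurationError):
            grow_tree(
                np.empty((0, 2)), np.empty(0), np.empty((0, 2)), np.empty(0),
                self.CFG, np.random.default_rng(0),
            )

    def test_estimation_labels_shape_nothing_but_leaf_fractions(self):
        rng = np.random.default_rng(3)
        Xs = rng.uniform(0, 1, (40, 4))
        ys = (Xs[:, 0] > 0.5).astype(int)
        Xe = rng.uniform(0, 1, (40, 4))
        ye = (Xe[:, 0] > 0.5).astype(int)
        cfg = BRFConfig(n_trees=1, p1=0.1, p2=0.1, min_split=4, bootstrap=False)
        t1 = grow_tree(Xs, ys, Xe, ye, cfg, np.random.default_rng(11))
        t2 = grow_tree(Xs, ys, Xe, 1 - ye, cfg, np.random.default_rng(11))
        assert t1.structure() == t2.structure()
        leaf_fracs = lambda n: (  # noqa: E731
            [n.positive_fraction] if n.is_leaf
            else leaf_fracs(n.left) + leaf_fracs(n.right)
        )
        assert leaf_fracs(t1) != leaf_fracs(t2)

    def test_empty_estimation_leaf_inherits_ancestor_fraction(self):
        # estimation samples all route right; the left leaf must inherit
        Xs = np.array([[0.0], [0.1], [0.9], [1.0]])
        ys = np.array([0, 0, 1, 1])
        Xe = np.array([[0.8], [0.95]])
        ye = np.array([1, 0])
        t = grow_tree(Xs, ys, Xe, ye, self.CFG, np.random.default_rng(0))
        assert not t.is_leaf
        assert t.left.estimation_count == 0
        assert t.left.positive_fraction == pytest.approx(0.5)  # root fraction


class TestForest:
    def planted(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (n, 5))
        y = (X[:, 1] + 0.2 * rng.normal(size=n) > 0.5).astype(int)
        return X, y

    def test_same_seed_reproduces_forest_exactly(self):
        X, y = self.planted()
        cfg = BRFConfig(n_trees=10, seed=4, min_split=5)
        assert fit(X, y, cfg).to_json() == fit(X, y, cfg).to_json()

    def test_single_tree_forest(self):
        X, y = self.planted()
        assert len(fit(X, y, BRFConfig(n_trees=1, min_split=5)).trees) == 1

    def test_single_class_labels_rejected(self):
        X, _ = self.planted()
        with pytest.raises(ConfigurationError):
            fit(X, np.ones(len(X)))

    def test_planted_signal_training_auc_above_09(self):
        from cnnbrf.evaluation import rank_auc

        X, y = self.planted(n=200, seed=1)
        model = fit(X, y, BRFConfig(n_trees=50, min_split=5, seed=0))
        s = model.predict_proba(X)
        assert rank_auc(s[y == 1], s[y == 0]) > 0.9

    def test_predict_mean_of_leaf_fractions(self):
        leaf1 = TreeNode(positive_fraction=1.0, estimation_count=1)
        leaf0 = TreeNode(positive_fraction=0.0, estimation_count=1)
        model = BRFModel(
            trees=[leaf1, leaf0], config=BRFConfig(n_trees=2), n_features=3
        )
        np.testing.assert_allclose(model.predict_proba(np.zeros((2, 3))), 0.5)

    def test_scores_bounded_and_shape_checked(self):
        X, y = self.planted()
        model = fit(X, y, BRFConfig(n_trees=5, min_split=5))
        s = model.predict_proba(np.random.default_rng(0).uniform(0, 1, (30, 5)))
        assert s.min() >= 0 and s.max() <= 1
        with pytest.raises(ConfigurationError):
            model.predict_proba(np.zeros((3, 4)))

    def test_json_roundtrip_preserves_predictions(self):
        X, y = self.planted()
        model = fit(X, y, BRFConfig(n_trees=5, min_split=5))
        back = BRFModel.from_json(model.to_json())
        np.testing.assert_array_equal(back.predict_proba(X), model.predict_proba(X))

    def test_prediction_variance_shrinks_with_forest_size(self):
        X, y = self.planted(n=100, seed=2)
        Xq = np.random.default_rng(9).uniform(0, 1, (40, 5))

        def variance(n_trees):
            preds = [
                fit(X, y, BRFConfig(n_trees=n_trees, min_split=5, seed=s)).predict_proba(Xq)
                for s in range(6)
            ]
            return np.var(np.stack(preds), axis=0).mean()

        assert variance(100) < variance(10)


class TestDegenerateLimitOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n,d", [(20, 3), (50, 5)])
    def test_equals_reference_gini_forest(self, seed, n, d):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 1, (n, d)).round(2)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        cfg = BRFConfig(
            n_trees=3, p1=0.0, p2=0.0, min_split=4, bootstrap=False,
            share_data=True, seed=seed,
        )
        model = fit(X, y, cfg)
        streams = np.random.SeedSequence(seed).spawn(cfg.n_trees)
        for t in range(cfg.n_trees):
            ref_rng = np.random.default_rng(streams[t])
            ref = reference_tree(X, y, cfg, ref_rng)
            assert trees_equal(ref, tree_to_tuple(model.trees[t]))
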