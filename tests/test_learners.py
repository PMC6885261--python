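"""Native base learners: gain-ratio tree, naive Bayes, k-NN, random forest."""

import math

import numpy as np
import pytest

import emgkit as ek
from emgkit.errors import ParameterError, TrainingError
from emgkit.learners import Dataset, weighted_resample


def make_ds(X, y, classes=("A", "B"), weights=None):
    return Dataset(np.atleast_2d(np.asarray(X, float).T).T.reshape(len(y), -1),
                   np.asarray(y), classes, weights)


def brute_force_root_split(X, y, w, K, min_leaf=1):
    """Exhaustive enumeration of all midpoint thresholds; C4.5 rule applied
    independently of the tree implementation."""
    candidates = []
    total = w.sum()

    def entropy(weights_per_class):
        tot = sum(weights_per_class)
        h = 0.0
        for c in weights_per_class:
            if c > 0:
                p = c / tot
                h -= p * math.log2(p)
        return h

    parent = [w[y == k].sum() for k in range(K)]
    h_parent = entropy(parent)
    for f in range(X.shape[1]):
        values = sorted(set(X[:, f]))
        for a, b in zip(values[:-1], values[1:]):
            thr = (a + b) / 2
            left = X[:, f] <= thr
            if left.sum() < min_leaf or (~left).sum() < min_leaf:
                continue
            wl = [w[left & (y == k)].sum() for k in range(K)]
            wr = [w[~left & (y == k)].sum() for k in range(K)]
            swl, swr = sum(wl), sum(wr)
            gain = h_parent - (swl * entropy(wl) + swr * entropy(wr)) / total
            split_info = entropy([swl, swr])
            candidates.append((f, thr, gain, gain / split_info))
    if not candidates:
        return None
    mean_gain = sum(c[2] for c in candidates) / len(candidates)
    eligible = [c for c in candidates if c[2] >= mean_gain - 1e-12 and c[2] > 1e-12]
    if not eligible:
        return None
    best = max(eligible, key=lambda c: c[3])
    return best[0], best[1]


class TestGainRatioTree:
    def test_perfect_binary_split(self):
        ds = make_ds([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        model = ek.train_gain_ratio_tree(ds)
        assert model.root.feature == 0
        assert model.root.threshold == pytest.approx(2.5)
        assert np.array_equal(model.predict(ds.X), ds.y)

    def test_pure_dataset_is_single_leaf(self):
        ds = make_ds([1.0, 2.0, 3.0], [0, 0, 0])
        model = ek.train_gain_ratio_tree(ds)
        assert model.root.feature is None
        assert model.predict(np.array([[99.0]]))[0] == 0

    def test_identical_rows_mixed_labels_majority_leaf(self):
        ds = make_ds([1.0, 1.0, 1.0], [0, 0, 1])
        model = ek.train_gain_ratio_tree(ds)
        assert model.root.feature is None
        assert model.predict(np.array([[1.0]]))[0] == 0

    def test_root_split_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            d = int(rng.integers(1, 3))
            X = np.round(rng.normal(size=(n, d)), 2)
            y = rng.integers(0, 2, size=n)
            ds = Dataset(X, y, ("A", "B"))
            model = ek.train_gain_ratio_tree(ds)
            want = brute_force_root_split(X, y, np.ones(n), 2)
            if want is None:
                assert model.root.feature is None
            else:
                assert model.root.feature == want[0]
                assert model.root.threshold == pytest.approx(want[1])

    def test_duplicating_instances_with_halved_weights_preserves_tree(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, size=20)
        base = ek.train_gain_ratio_tree(Dataset(X, y, ("A", "B")))
        dup = Dataset(
            np.vstack([X, X]), np.concatenate([y, y]), ("A", "B"), np.full(40, 0.5)
        )
        doubled = ek.train_gain_ratio_tree(dup)

        def structure(node):
            if node.feature is None:
                return ("leaf", tuple(np.round(node.dist, 12)))
            return (node.feature, round(node.threshold, 12),
                    structure(node.left), structure(node.right))

        assert structure(base.root) == structure(doubled.root)

    def test_score_is_distribution_and_argmax_consistent(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 3, size=50)
        model = ek.train_gain_ratio_tree(Dataset(X, y, ek.CLASSES))
        q = rng.normal(size=(20, 4))
        s = model.score(q)
        assert np.all(s >= 0)
        np.testing.assert_allclose(s.sum(axis=1), 1.0)
        assert np.array_equal(np.argmax(s, axis=1), model.predict(q))


class TestNaiveBayes:
    def test_symmetric_two_class_query_is_even(self):
        ds = make_ds([-1.0, -1.0, 1.0, 1.0], [0, 0, 1, 1])
        model = ek.train_naive_bayes(ds)
        s = model.score(np.array([[0.0]]))[0]
        assert s[0] == pytest.approx(0.5, abs=1e-12)
        assert s[1] == pytest.approx(0.5, abs=1e-12)

    def test_well_separated_class_mean_query(self):
        # classes at means +-3 with sd 0.5: querying a mean is near-certain
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-3, 0.5, 50), rng.normal(3, 0.5, 50)])
        y = np.array([0] * 50 + [1] * 50)
        model = ek.train_naive_bayes(make_ds(X, y))
        assert model.score(np.array([[-3.0]]))[0, 0] > 0.99
        assert model.score(np.array([[3.0]]))[0, 1] > 0.99

    def test_prior_dominance_under_identical_likelihoods(self):
        # 9:1 weighting with identical feature distributions
        X = np.array([[0.0]] * 10)
        y = np.array([0] * 5 + [1] * 5)
        w = np.array([1.8] * 5 + [0.2] * 5)
        model = ek.train_naive_bayes(Dataset(X, y, ("A", "B"), w))
        assert model.predict(np.array([[0.0]]))[0] == 0
        assert model.score(np.array([[0.0]]))[0, 0] == pytest.approx(0.9, abs=1e-9)

    def test_absent_class_rejected(self):
        ds = Dataset(np.zeros((4, 1)), np.zeros(4, dtype=int), ("A", "B"))
        with pytest.raises(TrainingError):
            ek.train_naive_bayes(ds)

    def test_matches_sklearn_gaussian_nb(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3)) + rng.integers(0, 3, size=60)[:, None]
        y = rng.integers(0, 3, size=60)
        mine = ek.train_naive_bayes(Dataset(X, y, ek.CLASSES), var_floor=1e-9)
        ref = GaussianNB(var_smoothing=0.0).fit(X, y)
        np.testing.assert_allclose(
            mine.score(X), ref.predict_proba(X), atol=1e-8
        )


class TestKnn:
    def test_nearest_neighbour(self):
        ds = make_ds([0.0, 1.0, 10.0], [0, 0, 1])
        model = ek.train_knn(ds, k=1, standardize=False)
        assert model.predict(np.array([[0.4]]))[0] == 0

    def test_majority_of_three(self):
        ds = make_ds([0.0, 1.0, 10.0], [0, 0, 1])
        model = ek.train_knn(ds, k=3, standardize=False)
        assert model.predict(np.array([[10.0]]))[0] == 0  # A,A,B majority

    def test_k_equals_n_predicts_global_majority(self):
        ds = make_ds([0.0, 1.0, 2.0, 10.0, 11.0], [1, 1, 1, 0, 0])
        model = ek.train_knn(ds, k=5, standardize=False)
        assert np.all(model.predict(np.array([[0.0], [100.0]])) == 1)

    def test_k_out_of_range(self):
        ds = make_ds([0.0, 1.0], [0, 1])
        with pytest.raises(ParameterError):
            ek.train_knn(ds, k=3)

    def test_matches_sklearn_predictions(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        mine = ek.train_knn(Dataset(X, y, ("A", "B")), k=5, standardize=False)
        ref = KNeighborsClassifier(n_neighbors=5).fit(X, y)
        q = rng.normal(size=(30, 4))
        assert np.array_equal(mine.predict(q), ref.predict(q))


class TestRandomTreeAndForest:
    def _ds(self, n=80, d=4, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        return Dataset(X, y, ("A", "B"))

    def test_full_feature_subset_equals_plain_tree(self):
        ds = self._ds()
        plain = ek.train_gain_ratio_tree(ds)
        rand = ek.train_random_tree(ds, ek.TreeSpec(features_per_split=ds.d), seed=3)
        assert np.array_equal(plain.predict(ds.X), rand.predict(ds.X))
        assert plain.root.feature == rand.root.feature
        assert plain.root.threshold == rand.root.threshold

    def test_seed_determinism(self):
        ds = self._ds()
        a = ek.train_random_tree(ds, seed=5)
        b = ek.train_random_tree(ds, seed=5)
        assert a.root.feature == b.root.feature
        assert np.array_equal(a.predict(ds.X), b.predict(ds.X))

    def test_seeds_can_change_root_on_redundant_features(self):
        # two copies of the same informative feature: the sampled subset decides
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        X = np.column_stack([x, x + 1e-9 * rng.normal(size=60)])
        y = (x > 0).astype(int)
        ds = Dataset(X, y, ("A", "B"))
        roots = {
            ek.train_random_tree(ds, ek.TreeSpec(features_per_split=1), seed=s).root.feature
            for s in range(20)
        }
        assert len(roots) > 1

    def test_forest_vote_fractions_sum_to_one(self):
        ds = self._ds()
        model = ek.train_random_forest(ds, ek.ForestSpec(n_trees=7), seed=0)
        s = model.score(ds.X)
        np.testing.assert_allclose(s.sum(axis=1), 1.0)
        assert np.array_equal(np.argmax(s, axis=1), model.predict(ds.X))

    def test_single_tree_no_bootstrap_equals_random_tree(self):
        ds = self._ds()
        forest = ek.train_random_forest(
            ds, ek.ForestSpec(n_trees=1, bootstrap=False), seed=9
        )
        assert np.array_equal(
            forest.predict(ds.X), forest.members[0].predict(ds.X)
        )

    def test_forest_separable_out_of_fold_accuracy(self):
        # linearly separable blobs, margin 2, sd 0.3
        rng = np.random.default_rng(11)
        X = np.vstack(
            [rng.normal(-1.0, 0.3, size=(100, 2)), rng.normal(1.0, 0.3, size=(100, 2))]
        )
        y = np.array([0] * 100 + [1] * 100)
        train = np.r_[0:80, 100:180]
        test = np.r_[80:100, 180:200]
        model = ek.train_random_forest(
            Dataset(X[train], y[train], ("A", "B")), ek.ForestSpec(n_trees=15), seed=2
        )
        assert (model.predict(X[test]) == y[test]).mean() >= 0.98


class TestWeightsAndResampling:
    def test_uniform_weight_resample_preserves_distribution(self):
        ds = Dataset(np.arange(10, dtype=float)[:, None], np.zeros(10, int), ("A",))
        out = weighted_resample(ds, np.ones(10), seed=0)
        assert out.n == 10
        assert set(out.X[:, 0]) <= set(ds.X[:, 0])

    def test_resample_concentrates_on_heavy_instances(self):
        ds = Dataset(np.arange(4, dtype=float)[:, None], np.zeros(4, int), ("A",))
        w = np.array([1e-9, 1e-9, 1e-9, 1.0])
        out = weighted_resample(ds, w, seed=1)
        assert np.all(out.X[:, 0] == 3.0)

    def test_sklearn_adapter_contract(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        model = ek.train_sklearn(LogisticRegression(), Dataset(X, y, ("A", "B")))
        s = model.score(X)
        np.testing.assert_allclose(s.sum(axis=1), 1.0)
        assert (model.predict(X) == y).mean() > 0.9
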