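"""Cross-validated classification, clustering and quality indices."""

import numpy as np
import pytest

from ontodist import (DistanceMatrix, EvalConfig, agglomerative_cluster,
                      cluster_quality, evaluate_all, feature_classify,
                      kmeans_cluster, knn_classify, scores, stratified_folds)


def block_matrix(sizes, within=0.0, between=1.0):
    """Tight diagnostic blocks: distance `within` inside, `between` across."""
    n = sum(sizes)
    labels = np.repeat([f"c{i}" for i in range(len(sizes))], sizes)
    v = np.full((n, n), between)
    same = labels[:, None] == labels[None, :]
    v[same] = within
    np.fill_diagonal(v, 0.0)
    ids = tuple(f"p{i}" for i in range(n))
    return DistanceMatrix(ids=ids, values=v, metric="jaccard"), labels


def random_matrix(n, seed):
    rng = np.random.default_rng(seed)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(ids=tuple(f"p{i}" for i in range(n)), values=v,
                          metric="jaccard")


class TestStratifiedFolds:
    def test_perfect_divisibility(self):
        labels = ["a"] * 10 + ["b"] * 10
        folds = stratified_folds(labels, 10, seed=0)
        for k in range(10):
            members = np.asarray(labels)[folds == k]
            assert len(members) == 2
            assert set(members) == {"a", "b"}

    def test_leave_one_out(self):
        labels = ["a", "b"] * 5
        folds = stratified_folds(labels, 10, seed=0)
        assert sorted(np.bincount(folds)) == [1] * 10

    def test_near_proportional_unbalanced(self):
        rng = np.random.default_rng(3)
        labels = rng.choice([f"c{i}" for i in range(8)], size=100,
                            p=np.array([20, 18, 15, 14, 12, 10, 6, 5]) / 100)
        folds = stratified_folds(labels, 5, seed=1)
        for cls in np.unique(labels):
            counts = np.bincount(folds[labels == cls], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_too_many_folds(self):
        with pytest.raises(ValueError):
            stratified_folds(["a", "b"], 3, seed=0)

    def test_deterministic(self):
        labels = ["a", "b", "c"] * 10
        f1 = stratified_folds(labels, 5, seed=9)
        f2 = stratified_folds(labels, 5, seed=9)
        np.testing.assert_array_equal(f1, f2)


class TestScores:
    def test_perfect(self):
        assert scores(["a", "b"], ["a", "b"]) == (100.0, 100.0)

    def test_majority_prediction_accuracy(self):
        acc, _ = scores(["a"] * 10, ["a"] * 5 + ["b"] * 5)
        assert acc == 50.0

    def test_macro_f1_hand_computed(self):
        """Class a has TP=3, FP=1, FN=2 -> F1_a = 6/9; class b gets 0."""
        truth = ["a"] * 5 + ["b"]
        pred = ["a", "a", "a", "b", "b", "a"]
        _, f1 = scores(pred, truth)
        assert f1 == pytest.approx(100 * (6 / 9 + 0) / 2, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scores([], [])


class TestKnn:
    def test_separated_blocks_perfect(self):
        d, labels = block_matrix([10, 10, 10])
        res = knn_classify(d, labels, EvalConfig(n_folds=5, seed=0))
        assert res.accuracy == 100.0

    def test_k1_nearest_same_label(self):
        d, labels = block_matrix([6, 6], within=0.1)
        res = knn_classify(d, labels, EvalConfig(knn_k=1, n_folds=3, seed=0))
        assert res.accuracy == 100.0

    def test_matches_sklearn_on_tie_free_matrix(self):
        from sklearn.neighbors import KNeighborsClassifier
        d = random_matrix(40, seed=5)
        rng = np.random.default_rng(5)
        labels = rng.choice(["a", "b", "c"], 40)
        cfg = EvalConfig(knn_k=3, n_folds=4, seed=2)
        folds = stratified_folds(labels, 4, seed=2)
        res = knn_classify(d, labels, cfg, folds)
        for k in range(4):
            train = np.flatnonzero(folds != k)
            test = np.flatnonzero(folds == k)
            sk = KNeighborsClassifier(n_neighbors=3, metric="precomputed")
            sk.fit(d.values[np.ix_(train, train)], labels[train])
            skpred = sk.predict(d.values[np.ix_(test, train)])
            # compare only where the vote is untied
            for i, p in zip(test, skpred):
                row = d.values[i, train]
                near = labels[train[np.argsort(row)[:3]]]
                vals, counts = np.unique(near, return_counts=True)
                if (counts == counts.max()).sum() == 1:
                    assert res.predictions[i] == p

    def test_fold_smaller_than_k(self):
        d, labels = block_matrix([2, 2])
        with pytest.raises(ValueError, match="fewer than k"):
            knn_classify(d, labels, EvalConfig(knn_k=5, n_folds=2, seed=0))


class TestFeatureClassifiers:
    def test_separable_logistic_regression(self):
        d, labels = block_matrix([12, 12])
        res = feature_classify(d, labels, "logistic_regression",
                               EvalConfig(n_folds=4, seed=0))
        assert res.accuracy == 100.0

    def test_constant_matrix_majority_rate(self):
        n = 30
        v = np.full((n, n), 0.5)
        np.fill_diagonal(v, 0.0)
        d = DistanceMatrix(ids=tuple(f"p{i}" for i in range(n)), values=v,
                           metric="jaccard")
        labels = np.array(["a"] * 20 + ["b"] * 10)
        res = feature_classify(d, labels, "logistic_regression",
                               EvalConfig(n_folds=5, seed=1))
        # no signal: predicts (close to) the majority class throughout
        assert res.accuracy == pytest.approx(100 * 20 / 30, abs=5)

    def test_random_forest_deterministic(self):
        d = random_matrix(30, seed=8)
        rng = np.random.default_rng(8)
        labels = rng.choice(["a", "b"], 30)
        cfg = EvalConfig(n_folds=3, seed=4)
        r1 = feature_classify(d, labels, "random_forest", cfg)
        r2 = feature_classify(d, labels, "random_forest", cfg)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)

    def test_unknown_classifier(self):
        d, labels = block_matrix([4, 4])
        with pytest.raises(ValueError, match="unknown classifier"):
            feature_classify(d, labels, "svm", EvalConfig(n_folds=2, seed=0))


def naive_ward_labels(values, n_clusters):
    """Reference Ward: naive Lance-Williams recurrence on squared distances."""
    n = len(values)
    d2 = values.astype(float) ** 2
    active = {i: [i] for i in range(n)}
    d = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(active) > n_clusters:
        (a, b), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = len(active[a]), len(active[b])
        merged = active.pop(a) + active.pop(b)
        new_d = {}
        for k, members in active.items():
            nk = len(members)
            dak = d[(min(a, k), max(a, k))]
            dbk = d[(min(b, k), max(b, k))]
            new_d[k] = ((na + nk) * dak + (nb + nk) * dbk
                        - nk * d[(min(a, b), max(a, b))]) / (na + nb + nk)
        d = {(min(i, j), max(i, j)): v for (i, j), v in d.items()
             if i in active and j in active}
        active[a] = merged
        for k, v in new_d.items():
            d[(min(a, k), max(a, k))] = v
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(active.values()):
        labels[members] = lab
    return labels


class TestClustering:
    def test_agglomerative_recovers_blocks(self):
        d, labels = block_matrix([8, 8])
        pred = agglomerative_cluster(d, 2)
        q = cluster_quality(pred, labels, d)
        assert q["adjusted_rand"] == pytest.approx(100)

    def test_agglomerative_singletons(self):
        d = random_matrix(6, seed=1)
        pred = agglomerative_cluster(d, 6)
        assert len(set(pred)) == 6

    def test_agglomerative_too_many_clusters(self):
        d = random_matrix(4, seed=1)
        with pytest.raises(ValueError):
            agglomerative_cluster(d, 5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ward_matches_naive_lance_williams(self, seed):
        """scipy-backed Ward agrees with a hand-rolled reference on random
        30-patient matrices (up to label permutation)."""
        from sklearn.metrics import adjusted_rand_score
        d = random_matrix(30, seed=seed)
        ours = agglomerative_cluster(d, 4)
        ref = naive_ward_labels(d.values, 4)
        assert adjusted_rand_score(ours, ref) == pytest.approx(1.0)

    def test_kmeans_recovers_blocks(self):
        d, labels = block_matrix([10, 10])
        pred = kmeans_cluster(d, 2, seed=0)
        q = cluster_quality(pred, labels, d)
        assert q["adjusted_rand"] == pytest.approx(100)

    def test_kmeans_deterministic(self):
        d = random_matrix(25, seed=3)
        np.testing.assert_array_equal(kmeans_cluster(d, 4, seed=9),
                                      kmeans_cluster(d, 4, seed=9))

    def test_kmeans_keeps_best_inertia(self):
        d = random_matrix(25, seed=4)
        labels, inertias = kmeans_cluster(d, 4, seed=2,
                                          return_inertias=True)
        from sklearn.metrics import pairwise_distances_argmin_min
        # returned solution's inertia equals the minimum over restarts
        centers = np.stack([d.values[labels == k].mean(axis=0)
                            for k in np.unique(labels)])
        _, dist = pairwise_distances_argmin_min(d.values, centers)
        assert (dist ** 2).sum() <= min(inertias) + 1e-6


class TestClusterQuality:
    def test_perfect_match(self):
        d, labels = block_matrix([5, 5, 5])
        q = cluster_quality(labels, labels, d)
        for name in ("adjusted_rand", "v_measure", "homogeneity",
                     "completeness"):
            assert q[name] == pytest.approx(100)

    def test_single_cluster(self):
        d, labels = block_matrix([5, 5])
        q = cluster_quality(np.zeros(10, dtype=int), labels, d)
        assert q["silhouette"] is None
        assert q["completeness"] == pytest.approx(100)
        assert q["homogeneity"] == pytest.approx(0)

    def test_label_permutation_invariance(self):
        d = random_matrix(20, seed=6)
        rng = np.random.default_rng(6)
        truth = rng.integers(0, 3, 20)
        pred = rng.integers(0, 3, 20)
        q1 = cluster_quality(pred, truth, d)
        q2 = cluster_quality((pred + 1) % 3, truth, d)
        for name, v in q1.items():
            assert q2[name] == pytest.approx(v)


class TestEvaluateAll:
    def test_tidy_shape(self):
        d, labels = block_matrix([6, 6, 6])
        frame = evaluate_all({"jaccard": d, "cosine": d}, labels,
                             EvalConfig(n_folds=3, n_clusters=3, seed=0))
        # per metric: 4 classifiers x 2 scores + 2 clusterers x 6 indices
        assert len(frame) == 2 * (4 * 2 + 2 * 6)
        assert set(frame.columns) == {"metric", "algorithm", "score_name",
                                      "value"}
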