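"""Classification and clustering evaluation over precomputed distance matrices.

The evaluation harness mirrors a standard patient-similarity study design:

* four classifiers — k-nearest neighbor (uniform weighting, k = 5, operating
  directly on the precomputed distances), plus naive Bayes, L2 logistic
  regression and a 10-tree random forest fed the distance-matrix rows as
  feature vectors — scored by accuracy and macro F1 under seeded stratified
  10-fold cross-validation, both on a 0-100 scale;
* two clusterers — Ward-linkage agglomerative clustering on the precomputed
  distances and k-means on the distance rows (10 restarts, best inertia) —
  scored by silhouette (precomputed distances), adjusted Rand index,
  adjusted mutual information, homogeneity, completeness and V-measure.

Feeding distance rows to the feature classifiers is the default
interpretation of "distance matrices were the input"; a
``features="binary_findings"`` switch accepts the raw binarized finding
vectors instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (adjusted_mutual_info_score, adjusted_rand_score,
                             completeness_score, f1_score, homogeneity_score,
                             silhouette_score, v_measure_score)
from sklearn.naive_bayes import GaussianNB

from .patients import DistanceMatrix

__all__ = [
    "EvalConfig", "ClassificationResult", "CLASSIFIERS", "CLUSTERERS",
    "stratified_folds", "knn_classify", "feature_classify", "scores",
    "agglomerative_cluster", "kmeans_cluster", "cluster_quality",
    "evaluate_all",
]

CLASSIFIERS = ("knn", "naive_bayes", "logistic_regression", "random_forest")
CLUSTERERS = ("agglomerative", "kmeans")


@dataclass(frozen=True)
class EvalConfig:
    """Hyperparameters of the evaluation harness.

    Defaults follow the common choices for this task family: uniform kNN
    with k = 5, 10 trees for the random forest, L2-regularized logistic
    regression, 10-fold stratified CV and an 8-cluster solution matching the
    number of diagnoses per test group.
    """

    knn_k: int = 5
    rf_trees: int = 10
    n_folds: int = 10
    n_clusters: int = 8
    seed: int = 0
    features: str = "distance_rows"  # or "binary_findings"

    def __post_init__(self):
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.features not in ("distance_rows", "binary_findings"):
            raise ValueError("features must be distance_rows|binary_findings")


@dataclass(frozen=True)
class ClassificationResult:
    """Cross-validated predictions with 0-100 accuracy and macro F1."""

    classifier: str
    accuracy: float
    macro_f1: float
    predictions: np.ndarray = field(repr=False)
    folds: np.ndarray = field(repr=False)


def stratified_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment (one fold id per patient).

    Each class's shuffled members are dealt round-robin across the folds,
    continuing from where the previous class stopped, so per-class fold
    counts differ by at most 1 and fold sizes stay near-equal. Unlike
    sklearn's StratifiedKFold this handles classes smaller than the fold
    count (down to leave-one-out) without error.
    """
    labels = np.asarray(labels)
    if n_folds > len(labels):
        raise ValueError("n_folds exceeds cohort size")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    start = 0
    for cls in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == cls))
        for i, p in enumerate(members):
            assignment[p] = (start + i) % n_folds
        start = (start + len(members)) % n_folds
    return assignment


def scores(predictions, truth) -> tuple[float, float]:
    """Accuracy and macro F1 on a 0-100 scale.

    Macro F1 averages per-class F1 without weighting; classes never
    predicted contribute zero.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(truth) == 0:
        raise ValueError("empty input")
    acc = 100.0 * float(np.mean(predictions == truth))
    f1 = 100.0 * f1_score(truth, predictions, average="macro",
                          zero_division=0)
    return acc, f1


def knn_classify(d: DistanceMatrix, labels, cfg: EvalConfig,
                 folds: np.ndarray | None = None) -> ClassificationResult:
    """k-nearest-neighbor classification on the precomputed distances.

    The k nearest training patients vote with equal weight; ties are broken
    by the smaller mean distance to the tied classes' neighbors, then by
    lexicographic label, so predictions are deterministic.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(d.ids):
        raise ValueError("labels not aligned with the distance matrix")
    if folds is None:
        folds = stratified_folds(labels, cfg.n_folds, cfg.seed)
    predictions = np.empty(len(labels), dtype=object)
    for k in np.unique(folds):
        train = np.flatnonzero(folds != k)
        test = np.flatnonzero(folds == k)
        if len(train) < cfg.knn_k:
            raise ValueError(
                f"fold {k} has fewer than k={cfg.knn_k} training patients")
        for i in test:
            row = d.values[i, train]
            nearest = train[np.argsort(row, kind="stable")[:cfg.knn_k]]
            predictions[i] = _vote(labels[nearest], d.values[i, nearest])
    acc, f1 = scores(predictions, labels)
    return ClassificationResult("knn", acc, f1, predictions, folds)


def _vote(neighbor_labels: np.ndarray, neighbor_dists: np.ndarray) -> str:
    counts: dict[str, int] = {}
    dist_sums: dict[str, float] = {}
    for lab, dist in zip(neighbor_labels, neighbor_dists):
        counts[lab] = counts.get(lab, 0) + 1
        dist_sums[lab] = dist_sums.get(lab, 0.0) + dist
    best = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == best]
    tied.sort(key=lambda lab: (dist_sums[lab] / counts[lab], lab))
    return tied[0]


def feature_classify(d: DistanceMatrix, labels, classifier: str,
                     cfg: EvalConfig, folds: np.ndarray | None = None,
                     features: np.ndarray | None = None,
                     ) -> ClassificationResult:
    """Cross-validated classification with distance rows as features.

    Each patient is represented by its distances to the current fold's
    training patients (test rows restricted to training columns, so no test
    information leaks into the representation). Pass ``features`` to use an
    alternative patient representation (e.g. binarized findings); it is then
    used as-is for both training and test rows.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(d.ids):
        raise ValueError("labels not aligned with the distance matrix")
    if folds is None:
        folds = stratified_folds(labels, cfg.n_folds, cfg.seed)
    predictions = np.empty(len(labels), dtype=object)
    for k in np.unique(folds):
        train = np.flatnonzero(folds != k)
        test = np.flatnonzero(folds == k)
        if len(np.unique(labels[train])) < 2:
            raise ValueError(f"fold {k}: training data has a single class")
        if features is None:
            x_train = d.values[np.ix_(train, train)]
            x_test = d.values[np.ix_(test, train)]
        else:
            x_train = features[train]
            x_test = features[test]
        model = _make_classifier(classifier, cfg)
        model.fit(x_train, labels[train])
        predictions[test] = model.predict(x_test)
    acc, f1 = scores(predictions, labels)
    return ClassificationResult(classifier, acc, f1, predictions, folds)


def _make_classifier(name: str, cfg: EvalConfig):
    if name == "naive_bayes":
        return GaussianNB()
    if name == "logistic_regression":
        # l1_ratio=0 with finite C is pure L2 regularization
        return LogisticRegression(l1_ratio=0.0, max_iter=2000)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=cfg.rf_trees,
                                      random_state=cfg.seed)
    raise ValueError(f"unknown classifier {name!r}; valid: "
                     f"{', '.join(c for c in CLASSIFIERS if c != 'knn')}")


def agglomerative_cluster(d: DistanceMatrix, n_clusters: int) -> np.ndarray:
    """Ward-linkage hierarchical clustering on the precomputed distances.

    The Lance-Williams Ward recurrence is applied directly to the given
    distances (treated as if Euclidean — heterodox for non-Euclidean metrics
    but standard practice for precomputed patient distances) and the tree is
    cut at ``n_clusters``. Deterministic.
    """
    if n_clusters > len(d.ids):
        raise ValueError("n_clusters exceeds cohort size")
    condensed = squareform(d.values, checks=False)
    tree = linkage(condensed, method="ward")
    return fcluster(tree, t=n_clusters, criterion="maxclust") - 1


def kmeans_cluster(d: DistanceMatrix, n_clusters: int, seed: int,
                   n_restarts: int = 10, return_inertias: bool = False):
    """k-means on the rows of the distance matrix treated as features.

    k-means needs coordinates, so each patient's row of distances serves as
    its feature vector. Runs ``n_restarts`` seeded initializations and keeps
    the lowest-inertia solution; deterministic given the seed.
    """
    if n_clusters > len(d.ids):
        raise ValueError("n_clusters exceeds cohort size")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best_labels, inertias = None, []
    for s in child_seeds:
        km = KMeans(n_clusters=n_clusters, n_init=1,
                    random_state=int(s % (2 ** 31)))
        lab = km.fit_predict(d.values)
        inertias.append(km.inertia_)
        if best_labels is None or km.inertia_ < min(inertias[:-1]):
            best_labels = lab
    if return_inertias:
        return best_labels, np.array(inertias)
    return best_labels


def cluster_quality(pred, truth, d: DistanceMatrix) -> dict[str, float | None]:
    """Standard external and internal cluster-quality indices, 0-100 scaled.

    Silhouette uses the precomputed distances and is reported as missing
    (None) when a single cluster makes it undefined. ARI and AMI are
    chance-corrected and may be negative.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(np.unique(pred)) < 2:
        sil = None
    else:
        sil = 100.0 * silhouette_score(d.values, pred, metric="precomputed")
    return {
        "silhouette": sil,
        "adjusted_rand": 100.0 * adjusted_rand_score(truth, pred),
        "adjusted_mutual_info": 100.0 * adjusted_mutual_info_score(
            truth, pred),
        "homogeneity": 100.0 * homogeneity_score(truth, pred),
        "completeness": 100.0 * completeness_score(truth, pred),
        "v_measure": 100.0 * v_measure_score(truth, pred),
    }


def evaluate_all(matrices: dict[str, DistanceMatrix], labels,
                 cfg: EvalConfig,
                 binary_features: np.ndarray | None = None) -> pd.DataFrame:
    """Run every classifier and clusterer on every metric's matrix.

    Returns a tidy frame with columns ``metric, algorithm, score_name,
    value``. With ``cfg.features == "binary_findings"`` the non-kNN
    classifiers use ``binary_features`` instead of distance rows.
    """
    labels = np.asarray(labels, dtype=object)
    rows = []
    for metric, d in matrices.items():
        folds = stratified_folds(labels, cfg.n_folds, cfg.seed)
        feats = None
        if cfg.features == "binary_findings":
            if binary_features is None:
                raise ValueError(
                    "binary_findings requires the binary feature matrix")
            feats = binary_features
        results = [knn_classify(d, labels, cfg, folds)]
        for name in ("naive_bayes", "logistic_regression", "random_forest"):
            results.append(
                feature_classify(d, labels, name, cfg, folds, feats))
        for res in results:
            rows.append((metric, res.classifier, "accuracy", res.accuracy))
            rows.append((metric, res.classifier, "macro_f1", res.macro_f1))
        clusterings = {
            "agglomerative": agglomerative_cluster(d, cfg.n_clusters),
            "kmeans": kmeans_cluster(d, cfg.n_clusters, cfg.seed),
        }
        for algo, pred in clusterings.items():
            for name, value in cluster_quality(pred, labels, d).items():
                rows.append((metric, algo, name, value))
    return pd.DataFrame(rows,
                        columns=["metric", "algorithm", "score_name", "value"])
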