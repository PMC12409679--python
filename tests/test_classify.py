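"""k-NN prediction, cross-validation bookkeeping and evaluation metrics."""

import numpy as np
import pytest

import spastemg as sg
from spastemg.classify import N_GRADES, knn_predict_batch
from spastemg.errors import ConfigurationError, DataError, DomainError, FormatError


def brute_force_knn(X_train, y_train, query, k):
    """Independent oracle: pure-Python exhaustive distance enumeration
    implementing the stated vote and tie-break contract."""
    dists = []
    for i, row in enumerate(X_train):
        d = sum((a - b) ** 2 for a, b in zip(row, query)) ** 0.5
        dists.append((d, i))
    dists.sort(key=lambda t: (t[0], t[1]))
    chosen = dists[:k]
    votes = {}
    for d, i in chosen:
        votes[y_train[i]] = votes.get(y_train[i], 0) + 1
    top = max(votes.values())
    tied = [lab for lab, c in votes.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    nearest = {
        lab: min(d for d, i in chosen if y_train[i] == lab) for lab in tied
    }
    best = min(nearest.values())
    return min(lab for lab, d in nearest.items() if d == best)


def clustered_dataset(n_per_class=8, spread=0.05, seed=0, separation=10.0):
    """Five well-separated grade clusters in 3 dimensions."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for g in range(N_GRADES):
        centre = np.full(3, g * separation)
        X.append(centre + spread * rng.standard_normal((n_per_class, 3)))
        y.extend([g] * n_per_class)
    return np.vstack(X), np.array(y)


class TestKNNPredict:
    def test_zero_distance_neighbour_wins_at_k1(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([3, 1])
        assert sg.knn_predict(X, y, np.array([1.0, 1.0]), 1) == 1

    def test_local_majority(self):
        X = np.array([[0.0], [0.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        assert sg.knn_predict(X, y, np.array([0.05]), 3) == 0

    def test_vote_tie_broken_by_lowest_ordinal_when_equidistant(self):
        # five training points on a unit circle around the query
        theta = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        X = np.column_stack([np.cos(theta), np.sin(theta)])
        y = np.array([0, 0, 1, 1, 2])
        assert sg.knn_predict(X, y, np.zeros(2), 5) == 0

    def test_vote_tie_broken_by_nearest_tied_class_member(self):
        X = np.array([[1.0], [3.0], [0.5], [4.0], [10.0]])
        y = np.array([0, 0, 1, 1, 2])
        # votes 2-2-1; nearest member of class 1 (0.5) beats class 0 (1.0)
        assert sg.knn_predict(X, y, np.array([0.0]), 5) == 1

    def test_k_exceeding_training_size_rejected(self):
        X, y = np.zeros((3, 2)), np.array([0, 1, 2])
        with pytest.raises(ConfigurationError):
            sg.knn_predict(X, y, np.zeros(2), 4)

    def test_dimension_mismatch_rejected(self):
        X, y = np.zeros((3, 2)), np.array([0, 1, 2])
        with pytest.raises(DomainError):
            sg.knn_predict(X, y, np.zeros(3), 1)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        d = int(rng.integers(1, 4))
        X = rng.uniform(-1, 1, size=(n, d))
        y = rng.integers(0, 5, size=n)
        k = int(rng.integers(1, n + 1))
        for _ in range(5):
            q = rng.uniform(-1, 1, size=d)
            assert sg.knn_predict(X, y, q, k) == brute_force_knn(
                X.tolist(), y.tolist(), q.tolist(), k
            )

    def test_agrees_with_sklearn_when_vote_unambiguous(self):
        from collections import Counter

        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(42)
        X = rng.uniform(-1, 1, size=(40, 3))
        y = rng.integers(0, 5, size=40)
        clf = KNeighborsClassifier(n_neighbors=5).fit(X, y)
        for q in rng.uniform(-1, 1, size=(25, 3)):
            dist = np.linalg.norm(X - q, axis=1)
            votes = Counter(y[np.argsort(dist, kind="stable")[:5]].tolist())
            top = max(votes.values())
            if sum(1 for c in votes.values() if c == top) == 1:
                assert sg.knn_predict(X, y, q, 5) == clf.predict(q[None])[0]


class TestSplits:
    def test_nine_to_one_split_counts(self):
        X, y = clustered_dataset(n_per_class=40)
        data = sg.LabeledDataset(X, y)
        train, test = sg.stratified_split(data, 36, 4, seed=1)
        assert len(train) == 180 and len(test) == 20
        assert all(c == 36 for c in train.class_counts.values())
        assert all(c == 4 for c in test.class_counts.values())
        assert set(map(tuple, train.X)).isdisjoint(set(map(tuple, test.X)))

    def test_split_determinism_and_seed_sensitivity(self):
        X, y = clustered_dataset(n_per_class=40)
        data = sg.LabeledDataset(X, y)
        a1, _ = sg.stratified_split(data, 36, 4, seed=5)
        a2, _ = sg.stratified_split(data, 36, 4, seed=5)
        b1, _ = sg.stratified_split(data, 36, 4, seed=6)
        np.testing.assert_array_equal(a1.X, a2.X)
        assert not np.array_equal(a1.X, b1.X)

    def test_insufficient_class_count_names_grade(self):
        X, y = clustered_dataset(n_per_class=39)
        with pytest.raises(DataError, match="39"):
            sg.stratified_split(sg.LabeledDataset(X, y), 36, 4, seed=0)

    def test_kfold_balanced_allocation(self):
        _, y = clustered_dataset(n_per_class=40)
        assignment = sg.stratified_kfold(y, folds=10, seed=0)
        for fold in range(10):
            members = y[assignment == fold]
            assert len(members) == 20
            assert all(np.sum(members == g) == 4 for g in range(5))

    def test_kfold_is_a_partition(self):
        _, y = clustered_dataset(n_per_class=13)
        assignment = sg.stratified_kfold(y, folds=10, seed=3)
        assert assignment.shape == y.shape
        assert set(assignment.tolist()) == set(range(10))

    def test_single_fold_rejected(self):
        with pytest.raises(ConfigurationError):
            sg.stratified_kfold(np.zeros(10, dtype=int), folds=1)


class TestCrossValidate:
    def test_every_sample_predicted_once(self):
        X, y = clustered_dataset(n_per_class=20, spread=3.0)
        cm, _, _ = sg.cross_validate(sg.LabeledDataset(X, y), k=5, folds=10, seed=0)
        assert cm.sum() == len(y)
        np.testing.assert_array_equal(cm.sum(axis=1), [20] * 5)

    def test_separable_clusters_perfect_accuracy(self):
        X, y = clustered_dataset(n_per_class=20, spread=0.01)
        cm, acc, _ = sg.cross_validate(sg.LabeledDataset(X, y), k=5, folds=10, seed=0)
        assert acc == 1.0
        np.testing.assert_array_equal(cm, np.diag([20] * 5))

    def test_mean_fold_accuracy_matches_aggregated_accuracy(self):
        # equal-sized folds make the two notions of accuracy coincide
        X, y = clustered_dataset(n_per_class=20, spread=8.0)
        cm, acc, _ = sg.cross_validate(sg.LabeledDataset(X, y), k=3, folds=10, seed=2)
        assert acc == pytest.approx(np.trace(cm) / cm.sum())

    def test_select_k_returns_grid_member_and_is_deterministic(self):
        X, y = clustered_dataset(n_per_class=12, spread=6.0, seed=4)
        data = sg.LabeledDataset(X, y)
        best, accs = sg.select_k(data, grid=(1, 3, 5, 7), folds=6, seed=0)
        assert best in (1, 3, 5, 7)
        assert set(accs) == {1, 3, 5, 7}
        assert sg.select_k(data, grid=(1, 3, 5, 7), folds=6, seed=0)[0] == best

    def test_select_k_single_grid(self):
        X, y = clustered_dataset(n_per_class=10)
        assert sg.select_k(sg.LabeledDataset(X, y), grid=(5,), folds=5, seed=0)[0] == 5


class TestMetrics:
    def test_perfect_classifier(self):
        report = sg.metrics(np.diag([4, 4, 4, 4, 4]))
        assert report.accuracy == 1.0
        np.testing.assert_allclose(report.precision, 1.0)
        np.testing.assert_allclose(report.f1, 1.0)

    def test_clean_class_hand_computation(self):
        # TP=37, FN=3, FP=0 -> precision 1, recall 0.925, F1 ~ 0.961
        cm = np.array([[37, 3], [0, 60]])
        report = sg.metrics(cm)
        assert report.precision[0] == pytest.approx(1.0)
        assert report.recall[0] == pytest.approx(0.925)
        assert report.f1[0] == pytest.approx(2 * 0.925 / 1.925)

    def test_noisy_class_hand_computation(self):
        # TP=30, FN=10, FP=22 -> precision 30/52, recall 0.75, F1 ~ 0.652
        cm = np.array([[30, 10], [22, 38]])
        report = sg.metrics(cm)
        assert report.precision[0] == pytest.approx(30 / 52)
        assert report.recall[0] == pytest.approx(0.75)
        assert report.f1[0] == pytest.approx(2 * (30 / 52) * 0.75 / (30 / 52 + 0.75))

    def test_never_predicted_class_flagged_not_inflated(self):
        cm = np.array([[0, 5], [0, 5]])
        report = sg.metrics(cm)
        assert report.undefined_precision[0]
        assert report.precision[0] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_recount_from_pairs(self, seed):
        rng = np.random.default_rng(seed)
        true = rng.integers(0, 5, size=100)
        pred = rng.integers(0, 5, size=100)
        cm = np.zeros((5, 5), dtype=int)
        for t, p in zip(true, pred):
            cm[t, p] += 1
        report = sg.metrics(cm)
        assert report.accuracy == pytest.approx(np.mean(true == pred))
        for c in range(5):
            tp = int(np.sum((true == c) & (pred == c)))
            fp = int(np.sum((true != c) & (pred == c)))
            fn = int(np.sum((true == c) & (pred != c)))
            assert report.tp[c] == tp and report.fp[c] == fp and report.fn[c] == fn
            if tp + fp:
                assert report.precision[c] == pytest.approx(tp / (tp + fp))

    def test_invalid_matrices_rejected(self):
        with pytest.raises(DomainError):
            sg.metrics(np.zeros((0, 0)))
        with pytest.raises(DomainError):
            sg.metrics(np.zeros((3, 3)))
        with pytest.raises(FormatError):
            sg.metrics(np.array([[1, -1], [0, 1]]))
        with pytest.raises(DomainError):
            sg.metrics(np.ones((2, 3)))

    def test_report_frame_shape(self):
        report = sg.metrics(np.diag([1, 2, 3, 4, 5]))
        frame = report.to_frame()
        assert list(frame.index) == ["TP", "FN", "FP", "Precision", "Recall", "F1-Score"]
        assert list(frame.columns) == ["MAS 0", "MAS 1", "MAS 1+", "MAS 2", "MAS 3"]


def random_wide_features(n_per_grade=40, seed=0, signal=0.0):
    """Feature table with optional planted grade signal."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = n_per_grade * 5
    labels = [sg.GRADE_LABELS[i // n_per_grade] for i in range(n)]
    ordinals = np.array([sg.encode_mas(l) for l in labels], dtype=float)
    cols = pd.MultiIndex.from_product([sg.CHANNELS, sg.FEATURES])
    data = {}
    for col in cols:
        data[col] = signal * ordinals + rng.standard_normal(n)
    return pd.DataFrame(data, columns=cols), labels


class TestCompareModels:
    def test_seven_models_share_fold_assignment(self):
        wide, labels = random_wide_features(n_per_grade=8, signal=2.0)
        accs, digest = sg.compare_models(wide, labels, seed=0, k=3, folds=4)
        assert set(accs) == {
            "single_channel_LB", "single_channel_SB", "single_channel_BR",
            "single_feature_rms", "single_feature_iemg", "single_feature_ea",
            "fused",
        }
        _, digest2 = sg.compare_models(wide, labels, seed=0, k=3, folds=4)
        assert digest == digest2

    def test_pure_noise_features_score_near_chance(self):
        wide, labels = random_wide_features(n_per_grade=40, seed=1, signal=0.0)
        accs, _ = sg.compare_models(wide, labels, seed=0, k=5, folds=10)
        se3 = 3 * np.sqrt(0.2 * 0.8 / 200)
        for name, acc in accs.items():
            assert abs(acc - 0.2) <= se3 + 0.02, (name, acc)

    def test_fold_safe_mode_completes_and_is_comparable(self):
        wide, labels = random_wide_features(n_per_grade=8, signal=2.0)
        accs, _ = sg.compare_models(wide, labels, seed=0, k=3, folds=4,
                                    mode="fold_safe")
        assert set(accs.keys()) >= {"fused", "single_channel_LB"}
        assert 0.0 <= accs["fused"] <= 1.0
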