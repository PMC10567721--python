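"""Patch classifiers, benchmark-relative cluster selection, majority voting."""

import numpy as np
import pytest

from gliopatch import (
    CLASSES,
    ClassifierConfig,
    ClusterSelection,
    predict_patient,
    select_clusters,
    train_patch_classifier,
)
from gliopatch.synthetic import SyntheticConfig, gen_feature_dataset


class TestTrainPatchClassifier:
    def test_separable_two_class_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 0.3, (40, 3)), rng.normal(5, 0.3, (40, 3))])
        y = np.array(["A2"] * 40 + ["GBM"] * 40)
        clf = train_patch_classifier(X, y)
        assert clf.accuracy(X, y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_patch_classifier(np.zeros((10, 2)), np.array(["A2"] * 10))

    def test_permuted_labels_give_chance_level(self):
        cfg = SyntheticConfig(seed=11, slides_per_class=10, patches_per_slide=30)
        fm, truth = gen_feature_dataset(cfg)
        rng = np.random.default_rng(0)
        y = truth["label"].to_numpy().copy()
        rng.shuffle(y)  # break any feature-label association
        n = fm.n
        tr = rng.random(n) < 0.8
        clf = train_patch_classifier(fm.X[tr], y[tr])
        acc = clf.accuracy(fm.X[~tr], y[~tr])
        p = 1.0 / 6.0
        sd = np.sqrt(p * (1 - p) / (~tr).sum())
        assert abs(acc - p) < 3 * sd

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 4))
        y = rng.choice(["A2", "O2", "GBM"], size=120)
        c1 = train_patch_classifier(X, y, config=ClassifierConfig(seed=7))
        c2 = train_patch_classifier(X.copy(), y.copy(), config=ClassifierConfig(seed=7))
        assert np.array_equal(c1.predict_proba(X), c2.predict_proba(X))

    def test_proba_rows_sum_to_one_with_absent_class_columns(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = rng.choice(["A2", "GBM"], size=60)
        clf = train_patch_classifier(X, y)
        P = clf.predict_proba(X)
        assert P.shape == (60, 6)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
        for absent in ("A3", "A4", "O2", "O3"):
            assert np.all(P[:, CLASSES.index(absent)] == 0.0)


class _StubClassifier:
    """Fixed-accuracy classifier for exercising the selection rule."""

    def __init__(self, acc: float):
        self._acc = acc

    def accuracy(self, X, y) -> float:
        return self._acc


class TestSelectClusters:
    def _run(self, accs, bench, n_per_cluster=10):
        ids = sorted(accs)
        cluster_ids = np.repeat(ids, n_per_cluster)
        n = len(cluster_ids)
        X = np.zeros((n, 2))
        y = np.array(["GBM"] * n)
        per = {k: _StubClassifier(a) for k, a in accs.items()}
        return select_clusters(per, _StubClassifier(bench), X, y, cluster_ids)

    def test_strictly_better_clusters_selected(self):
        sel = self._run({1: 0.52, 2: 0.71, 3: 0.66, 4: 0.40}, bench=0.60)
        assert sel.selected == {2, 3}
        assert sel.benchmark_accuracy == 0.60
        assert not sel.fallback_used

    def test_fallback_to_single_best_with_warning(self):
        with pytest.warns(UserWarning, match="benchmark"):
            sel = self._run({1: 0.3, 2: 0.5, 3: 0.4}, bench=0.6)
        assert sel.selected == {2}
        assert sel.fallback_used

    def test_equality_excluded(self):
        sel = self._run({1: 0.60, 2: 0.70}, bench=0.60)
        assert sel.selected == {2}

    def test_empty_validation_cluster_excluded(self):
        cluster_ids = np.array([1] * 10 + [2] * 10)
        X = np.zeros((20, 2))
        y = np.array(["GBM"] * 20)
        per = {1: _StubClassifier(0.9), 2: _StubClassifier(0.9), 7: _StubClassifier(1.0)}
        sel = select_clusters(per, _StubClassifier(0.5), X, y, cluster_ids)
        assert 7 not in sel.per_cluster_accuracy
        assert sel.selected == {1, 2}

    def test_roundtrip(self):
        sel = self._run({1: 0.7, 2: 0.4}, bench=0.5)
        back = ClusterSelection.from_dict(sel.to_dict())
        assert back.selected == sel.selected
        assert back.benchmark_accuracy == sel.benchmark_accuracy


def _proba(votes, n_classes=6):
    """One-hot-ish probability rows voting the given class indices."""
    P = np.full((len(votes), n_classes), 0.02)
    for i, v in enumerate(votes):
        P[i, v] = 1.0 - 0.02 * (n_classes - 1)
    return P


class TestPredictPatient:
    def test_modal_class_wins(self):
        votes = [5] * 12 + [0] * 5 + [3] * 1  # GBM:12, A2:5, O2:1
        pred = predict_patient("p", _proba(votes))
        assert pred.predicted == "GBM"
        assert pred.votes == {"A2": 5, "A3": 0, "A4": 0, "O2": 1, "O3": 0, "GBM": 12}
        assert pred.n_patches_used == 18

    def test_vote_tie_broken_by_mean_probability(self):
        P = np.zeros((8, 6))
        P[:4, 0] = 0.61  # A2 votes, mean proba 0.61
        P[:4, 1] = 0.39
        P[4:, 1] = 0.58  # A3 votes, mean proba 0.58
        P[4:, 0] = 0.42
        pred = predict_patient("p", P)
        assert pred.votes["A2"] == 4 and pred.votes["A3"] == 4
        assert pred.predicted == "A2"

    def test_remaining_tie_broken_by_class_order(self):
        P = np.zeros((2, 6))
        P[0, 1] = 1.0  # A3
        P[1, 0] = 1.0  # A2; symmetric mean probabilities
        pred = predict_patient("p", P)
        assert pred.predicted == "A2"

    def test_only_selected_clusters_vote(self):
        sel = ClusterSelection(0.5, {0: 0.7, 1: 0.4}, frozenset({0}))
        votes = [5, 5, 0]  # two GBM patches in cluster 0, one A2 in cluster 1
        pred = predict_patient("p", _proba(votes), [0, 0, 1], sel)
        assert pred.predicted == "GBM"
        assert pred.n_patches_used == 2
        assert pred.votes["A2"] == 0

    def test_fallback_when_no_patch_in_selected_clusters(self):
        sel = ClusterSelection(0.5, {3: 0.9}, frozenset({3}))
        votes = [0, 0, 5]
        pred = predict_patient("p", _proba(votes), [1, 1, 2], sel)
        assert pred.fallback_all_patches
        assert pred.n_patches_used == 3
        assert pred.predicted == "A2"  # all-patch majority

    def test_zero_patches_rejected(self):
        with pytest.raises(ValueError):
            predict_patient("p", np.zeros((0, 6)))

    def test_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(8)
        P = rng.dirichlet(np.ones(6), size=15)
        cids = rng.integers(0, 3, 15)
        sel = ClusterSelection(0.5, {0: 0.7, 1: 0.6, 2: 0.4}, frozenset({0, 1}))
        base = predict_patient("p", P, cids, sel)
        perm = rng.permutation(15)
        shuffled = predict_patient("p", P[perm], cids[perm], sel)
        assert shuffled.predicted == base.predicted
        assert shuffled.votes == base.votes
        doubled = predict_patient("p", np.vstack([P, P]), np.concatenate([cids, cids]), sel)
        assert doubled.predicted == base.predicted
        assert doubled.n_patches_used == 2 * base.n_patches_used
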