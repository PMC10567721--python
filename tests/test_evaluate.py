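"""One-vs-rest metrics, DeLong test, fold plans, epoch selection."""

import numpy as np
import pytest

from gliopatch import (
    delong_test,
    early_stop_rule,
    make_folds,
    ovr_report,
    select_best_fold,
)
from gliopatch.evaluate import delong_se

from conftest import auc_pair_counting


def _binary_P(scores):
    s = np.asarray(scores, dtype=float)
    return np.column_stack([s, 1.0 - s])


class TestOvrReport:
    def test_perfectly_ranked_auc_one(self):
        y = ["pos", "pos", "neg", "neg"]
        rep = ovr_report(y, _binary_P([0.9, 0.8, 0.2, 0.1]), classes=("pos", "neg"))
        assert rep.per_class["pos"]["auc"] == 1.0

    def test_reversed_ranking_auc_zero(self):
        rep = ovr_report(["pos", "neg"], _binary_P([0.3, 0.7]), classes=("pos", "neg"))
        assert rep.per_class["pos"]["auc"] == 0.0

    def test_worked_example_with_ties(self):
        # pairs: (0.8 vs 0.8 -> 1/2) + (0.8 vs 0.2 -> 1) + (0.3 vs 0.8 -> 0)
        # + (0.3 vs 0.2 -> 1), over 4 pairs = 0.625
        y = ["pos", "pos", "neg", "neg"]
        rep = ovr_report(y, _binary_P([0.8, 0.3, 0.8, 0.2]), classes=("pos", "neg"))
        assert rep.per_class["pos"]["auc"] == pytest.approx(0.625, abs=1e-12)

    def test_auc_matches_pair_counting_multiclass(self):
        rng = np.random.default_rng(0)
        n, C = 150, 6
        P = rng.dirichlet(np.ones(C), size=n)
        classes = ("A2", "A3", "A4", "O2", "O3", "GBM")
        y = rng.choice(classes, size=n)
        rep = ovr_report(y, P, classes)
        for i, cls in enumerate(classes):
            expected = auc_pair_counting(y == cls, P[:, i])
            assert rep.per_class[cls]["auc"] == pytest.approx(expected, abs=1e-12)

    def test_constant_scores(self):
        y = np.array(["pos"] * 30 + ["neg"] * 70)
        P = np.full((100, 2), 0.5)
        rep = ovr_report(y, P, classes=("pos", "neg"))
        assert rep.per_class["pos"]["auc"] == pytest.approx(0.5)
        precision, recall, _ = rep.pr_curves["pos"]
        assert precision[recall == 1.0][0] == pytest.approx(0.3)  # prevalence

    def test_absent_class_reported_none_with_warning(self):
        y = ["A2", "A2", "GBM"]
        P = np.full((3, 6), 1 / 6)
        with pytest.warns(UserWarning, match="absent"):
            rep = ovr_report(y, P)
        assert rep.per_class["O3"]["auc"] is None
        # macro averages only the defined classes
        assert not np.isnan(rep.macro_auc)

    def test_confusion_rows_equal_supports(self):
        rng = np.random.default_rng(3)
        classes = ("A2", "A3", "A4", "O2", "O3", "GBM")
        y = rng.choice(classes, size=120)
        P = rng.dirichlet(np.ones(6), size=120)
        rep = ovr_report(y, P, classes)
        for cls in classes:
            assert rep.confusion.loc[cls].sum() == np.sum(y == cls)
            assert rep.per_class[cls]["support"] == np.sum(y == cls)

    def test_unnormalised_rows_rejected(self):
        with pytest.raises(ValueError):
            ovr_report(["pos", "neg"], np.array([[0.9, 0.3], [0.5, 0.5]]),
                       classes=("pos", "neg"))


class TestDelong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 20 + [0] * 20)
        s = rng.normal(y, 1.0)
        res = delong_test(y, s, s)
        assert res.auc1 == res.auc2
        assert res.p == 1.0

    def test_auc_matches_rank_statistic_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        s1 = rng.normal(y, 1.0)
        s2 = rng.normal(y, 2.0)
        res = delong_test(y, s1, s2)
        assert res.auc1 == pytest.approx(auc_pair_counting(y, s1), abs=1e-12)
        assert res.auc2 == pytest.approx(auc_pair_counting(y, s2), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 30 + [0] * 30)
        s1 = rng.normal(y, 1.0)
        s2 = rng.normal(y, 1.5)
        r12 = delong_test(y, s1, s2)
        r21 = delong_test(y, s2, s1)
        assert r12.z == pytest.approx(-r21.z)
        assert r12.p == pytest.approx(r21.p)

    def test_zero_variance_unequal_aucs(self):
        y = np.array([1, 1, 0, 0])
        s1 = np.array([0.9, 0.8, 0.2, 0.1])  # AUC 1
        s2 = np.array([0.1, 0.2, 0.8, 0.9])  # AUC 0
        with pytest.warns(UserWarning):
            res = delong_test(y, s1, s2)
        assert res.p == 0.0

    def test_se_close_to_paired_bootstrap(self):
        rng = np.random.default_rng(4)
        n = 50
        y = np.array([1] * n + [0] * n)
        latent = rng.normal(y, 1.0)
        s1 = latent + rng.normal(0, 0.5, 2 * n)
        s2 = latent + rng.normal(0, 0.8, 2 * n)
        se = delong_se(y, s1, s2)
        B = 500  # the acceptance suite runs the full B=2000 check
        deltas = []
        for _ in range(B):
            idx = np.concatenate(
                [rng.choice(n, n), n + rng.choice(n, n)]
            )
            d = delong_test(y[idx], s1[idx], s2[idx])
            deltas.append(d.auc1 - d.auc2)
        boot = np.std(deltas, ddof=1)
        assert abs(se - boot) / boot < 0.25


class TestMakeFolds:
    def test_balanced_sixty_patients(self):
        classes = ["A2", "A3", "A4", "O2", "O3", "GBM"]
        pids = [f"p{i}" for i in range(60)]
        labels = [classes[i % 6] for i in range(60)]
        plan = make_folds(pids, labels, n_folds=5, seed=0)
        for f in range(5):
            fold = plan.fold_patients(f)
            assert len(fold) == 12
            fold_labels = [labels[pids.index(p)] for p in fold]
            assert all(fold_labels.count(c) == 2 for c in classes)

    def test_same_seed_identical_plan(self):
        pids = [f"p{i}" for i in range(30)]
        labels = ["A2" if i % 2 else "GBM" for i in range(30)]
        assert make_folds(pids, labels, seed=3).assignments == \
            make_folds(pids, labels, seed=3).assignments

    def test_different_seeds_differ_but_stay_stratified(self):
        pids = [f"p{i}" for i in range(40)]
        labels = ["A2" if i % 2 else "GBM" for i in range(40)]
        p1 = make_folds(pids, labels, seed=1)
        p2 = make_folds(pids, labels, seed=2)
        assert p1.assignments != p2.assignments
        for plan in (p1, p2):
            for f in range(5):
                fold_labels = [labels[pids.index(p)] for p in plan.fold_patients(f)]
                assert abs(fold_labels.count("A2") - 4) <= 1

    def test_small_class_error_names_class(self):
        pids = [f"p{i}" for i in range(12)]
        labels = ["GBM"] * 9 + ["O3"] * 3
        with pytest.raises(ValueError, match="O3"):
            make_folds(pids, labels, n_folds=5)

    def test_split_ratio(self):
        pids = [f"p{i}" for i in range(50)]
        labels = ["A2" if i % 2 else "GBM" for i in range(50)]
        plan = make_folds(pids, labels, n_folds=5, seed=0)
        train, val = plan.split(0)
        assert len(val) == 10 and len(train) == 40  # 4:1


class TestEarlyStop:
    def test_monotonic_decreasing_runs_to_max(self):
        losses = np.linspace(2.0, 0.5, 150)
        res = early_stop_rule(losses)
        assert res.stop_epoch == 150
        assert res.selected_epoch == 150
        assert res.best_window == (141, 150)

    def test_clear_minimum_plateau_selected(self):
        losses = np.concatenate(
            [np.linspace(2.0, 1.0, 59), np.full(10, 0.2), np.linspace(1.0, 1.5, 81)]
        )
        res = early_stop_rule(losses)
        # moving average is minimal on the window covering epochs 60-69
        assert res.best_window == (60, 69)
        assert res.selected_epoch == 69
        assert res.stop_epoch == 79  # confirmed after 10 non-improving epochs
        # brute-force moving-average scan agrees
        avgs = {
            e: losses[e - 10 : e].mean() for e in range(50, res.stop_epoch + 1)
        }
        assert res.selected_epoch == min(avgs, key=avgs.get)

    def test_history_shorter_than_window(self):
        res = early_stop_rule([1.0, 0.9, 0.8], window=10)
        assert res.selected_epoch is None and res.stop_epoch is None

    def test_desk_scale_parameters(self):
        losses = [3, 2, 1, 2, 3, 4, 5, 6]
        res = early_stop_rule(losses, min_epochs=2, max_epochs=8, window=2, patience=2)
        assert res.best_window == (2, 3)
        assert res.selected_epoch == 3
        assert res.stop_epoch == 5


class TestSelectBestFold:
    def test_argmax(self):
        assert select_best_fold([0.91, 0.95, 0.93, 0.90, 0.94]) == 1

    def test_all_equal_first(self):
        assert select_best_fold([0.9, 0.9, 0.9]) == 0

    def test_single_fold(self):
        assert select_best_fold([0.77]) == 0
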