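"""Evaluation statistics and cross-validation orchestration.

One-vs-rest ROC/AUC, PR curves, threshold metrics from argmax predictions,
the DeLong test for correlated AUCs, stratified K-fold plans at a 4:1
train:validation ratio, and the epoch-selection rule used when training an
iterative learner (minimum epochs, 10-epoch moving-average validation loss,
hard maximum).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .patchmodel import CLASSES

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------------
# One-vs-rest report
# ----------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-class one-vs-rest metrics plus curves and the confusion matrix."""

    classes: tuple
    per_class: dict            # class -> {auc, accuracy, sensitivity, specificity, f1, support}
    macro_auc: float
    confusion: pd.DataFrame    # rows = true class, columns = predicted class
    roc_curves: dict           # class -> (fpr, tpr, thresholds)
    pr_curves: dict            # class -> (precision, recall, thresholds)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "macro_auc": self.macro_auc,
            "per_class": self.per_class,
            "confusion": self.confusion.values.tolist(),
        }


def ovr_report(
    y_true: Sequence[str],
    P: np.ndarray,
    classes: Sequence[str] = CLASSES,
) -> EvalReport:
    """One-vs-rest evaluation of a probability matrix against true labels.

    AUC uses the rank statistic with ties counted 1/2 (the Mann-Whitney
    convention). Threshold metrics (accuracy, sensitivity, specificity, F1)
    come from argmax class assignments. A class absent from ``y_true`` has an
    undefined AUC, reported as None with a warning and excluded from the
    macro average.
    """
    y = np.asarray(y_true)
    P = np.asarray(P, dtype=float)
    classes = tuple(classes)
    if P.ndim != 2 or P.shape[1] != len(classes):
        raise ValueError(f"P must be n x {len(classes)}")
    if P.shape[0] != y.shape[0]:
        raise ValueError("y_true and P must align")
    row_sums = P.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 within 1e-6")
    pred = np.asarray([classes[i] for i in np.argmax(P, axis=1)])
    n = y.shape[0]
    per_class: dict = {}
    aucs = []
    roc_curves: dict = {}
    pr_curves: dict = {}
    for i, cls in enumerate(classes):
        pos = y == cls
        support = int(pos.sum())
        entry: dict = {"support": support}
        if support == 0 or support == n:
            warnings.warn(f"class {cls} absent from one side of y_true; AUC undefined")
            entry.update(auc=None)
        else:
            scores = P[:, i]
            entry["auc"] = float(roc_auc_score(pos.astype(int), scores))
            aucs.append(entry["auc"])
            roc_curves[cls] = roc_curve(pos.astype(int), scores)
            pr_curves[cls] = precision_recall_curve(pos.astype(int), scores)
        pred_pos = pred == cls
        tp = int(np.sum(pos & pred_pos))
        fn = int(np.sum(pos & ~pred_pos))
        fp = int(np.sum(~pos & pred_pos))
        tn = int(np.sum(~pos & ~pred_pos))
        entry["accuracy"] = (tp + tn) / n
        entry["sensitivity"] = tp / (tp + fn) if tp + fn else None
        entry["specificity"] = tn / (tn + fp) if tn + fp else None
        entry["f1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        per_class[cls] = entry
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    cm = confusion_matrix(y, pred, labels=list(classes))
    confusion = pd.DataFrame(cm, index=list(classes), columns=list(classes))
    return EvalReport(classes, per_class, macro_auc, confusion, roc_curves, pr_curves)


# ----------------------------------------------------------------------------
# DeLong test
# ----------------------------------------------------------------------------

@dataclass
class DelongResult:
    auc1: float
    auc2: float
    z: float
    p: float


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks of x (average rank over ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.shape[0]
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _auc_components(y: np.ndarray, scores: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC via midrank placements plus DeLong structural components.

    Returns (auc, V10 over positives, V01 over negatives).
    """
    pos = scores[y]
    neg = scores[~y]
    m, n = pos.shape[0], neg.shape[0]
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # per-positive components
    v01 = 1.0 - (tz[m:] - ty) / m    # per-negative components
    return float(auc), v10, v01


def delong_test(
    y: Sequence,
    s1: Sequence[float],
    s2: Sequence[float],
    paired: bool = True,
) -> DelongResult:
    """DeLong comparison of two (correlated) ROC AUCs on binary labels.

    AUCs are computed via midrank placements; the covariance of the paired
    AUCs comes from the DeLong structural components; z = dAUC / se and the
    two-sided p-value is taken from the standard normal. With zero variance
    the result is p = 1 when the AUCs are equal and p = 0 (with a warning)
    otherwise.
    """
    yb = np.asarray(y).astype(bool)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if not yb.any() or yb.all():
        raise ValueError("both classes must be present in y")
    if paired and (s1.shape != yb.shape or s2.shape != yb.shape):
        raise ValueError("paired scores must have the same length as y")
    auc1, v10_1, v01_1 = _auc_components(yb, s1)
    auc2, v10_2, v01_2 = _auc_components(yb, s2)
    m, n = v10_1.shape[0], v01_1.shape[0]
    if paired:
        s10 = np.cov(np.vstack([v10_1, v10_2]))
        s01 = np.cov(np.vstack([v01_1, v01_2]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
    else:
        var = v10_1.var(ddof=1) / m + v01_1.var(ddof=1) / n
        var += v10_2.var(ddof=1) / m + v01_2.var(ddof=1) / n
    delta = auc1 - auc2
    if var <= 0:
        if delta == 0:
            return DelongResult(auc1, auc2, 0.0, 1.0)
        warnings.warn("zero DeLong variance with unequal AUCs; p set to 0")
        return DelongResult(auc1, auc2, float(np.sign(delta)) * float("inf"), 0.0)
    z = delta / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return DelongResult(auc1, auc2, float(z), float(p))


def delong_se(y: Sequence, s1: Sequence[float], s2: Sequence[float]) -> float:
    """Standard error of the paired AUC difference under the DeLong model."""
    yb = np.asarray(y).astype(bool)
    a1, v10_1, v01_1 = _auc_components(yb, np.asarray(s1, dtype=float))
    a2, v10_2, v01_2 = _auc_components(yb, np.asarray(s2, dtype=float))
    m, n = v10_1.shape[0], v01_1.shape[0]
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    return float(np.sqrt(max(var, 0.0)))


# ----------------------------------------------------------------------------
# Fold plans
# ----------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Validation-fold assignment per patient under stratified sampling."""

    assignments: dict          # patient_id -> fold index (0-based)
    n_folds: int
    seed: int

    def fold_patients(self, fold: int) -> list:
        return [p for p, f in self.assignments.items() if f == fold]

    def split(self, fold: int) -> Tuple[list, list]:
        """(train_patients, validation_patients) for one fold."""
        val = self.fold_patients(fold)
        train = [p for p, f in self.assignments.items() if f != fold]
        return train, val

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.assignments), "fold": list(self.assignments.values())}
        )


def make_folds(
    patient_ids: Sequence[str],
    labels: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    strata: Optional[Sequence[str]] = None,
) -> FoldPlan:
    """Stratified fold plan: each fold's validation share is ~1/n_folds (4:1).

    Per-fold class counts differ from exact proportionality by at most one
    patient. A class with fewer members than folds raises an error naming it.
    """
    pids = list(map(str, patient_ids))
    y = np.asarray([str(v) for v in labels])
    if len(pids) != len(y):
        raise ValueError("patient_ids and labels must align")
    if len(set(pids)) != len(pids):
        raise ValueError("patient_ids must be unique")
    strat = y if strata is None else np.asarray([f"{a}|{b}" for a, b in zip(y, strata)])
    values, counts = np.unique(strat, return_counts=True)
    for v, c in zip(values, counts):
        if c < n_folds:
            raise ValueError(f"class {v!r} has only {c} patients, fewer than {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments: dict = {}
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(pids)), strat)):
        for i in val_idx:
            assignments[pids[i]] = fold
    return FoldPlan(assignments, n_folds, seed)


# ----------------------------------------------------------------------------
# Epoch selection rule
# ----------------------------------------------------------------------------

@dataclass
class EarlyStopResult:
    stop_epoch: Optional[int]       # 1-based epoch at which training halts
    selected_epoch: Optional[int]   # last epoch of the best moving-average window
    best_window: Optional[Tuple[int, int]]  # 1-based inclusive (start, end)
    best_average: Optional[float]


def early_stop_rule(
    loss_history: Sequence[float],
    min_epochs: int = 50,
    max_epochs: int = 150,
    window: int = 10,
    patience: Optional[int] = None,
) -> EarlyStopResult:
    """Epoch selection from a per-epoch validation-loss history.

    After at least ``min_epochs`` epochs, the ``window``-epoch moving average
    of validation loss is tracked; the retained model is the final epoch of
    the window with the lowest average (ties to the earliest window). A
    minimum counts as confirmed once no better window has appeared for
    ``patience`` epochs (default: ``window``), at which point training stops;
    otherwise it runs to ``max_epochs``. Histories shorter than the window
    yield no selection.
    """
    patience = window if patience is None else patience
    losses = np.asarray(loss_history, dtype=float)[:max_epochs]
    n = losses.shape[0]
    if n < window:
        return EarlyStopResult(None, None, None, None)
    first_end = max(min_epochs, window)  # 1-based epoch index of first eligible window end
    best_avg = np.inf
    best_end = None
    stop_epoch = None
    for end in range(first_end, n + 1):
        avg = losses[end - window : end].mean()
        if avg < best_avg:
            best_avg = avg
            best_end = end
        elif best_end is not None and end - best_end >= patience:
            stop_epoch = end
            break
    if best_end is None:
        # history ended before any eligible window
        return EarlyStopResult(n if n >= max_epochs else None, None, None, None)
    if stop_epoch is None:
        stop_epoch = n
    return EarlyStopResult(
        stop_epoch=stop_epoch,
        selected_epoch=best_end,
        best_window=(best_end - window + 1, best_end),
        best_average=float(best_avg),
    )


def select_best_fold(macro_aucs: Sequence[float]) -> int:
    """0-based index of the fold with the highest macro-average AUC.

    Ties resolve to the lowest fold index.
    """
    arr = np.asarray(macro_aucs, dtype=float)
    if arr.size == 0:
        raise ValueError("no folds to select from")
    return int(np.argmax(arr))
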