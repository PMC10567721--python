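"""Patch-level classifiers, benchmark-relative cluster selection, and
patient-level majority voting.

One classifier is trained per patch cluster plus an all-patch benchmark;
clusters whose validation accuracy strictly exceeds the benchmark's are
selected (globally, one set per model). The final classifier is trained on
the union of selected clusters, and patient predictions are the modal argmax
class among that patient's patches in selected clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

CLASSES = ("A2", "A3", "A4", "O2", "O3", "GBM")


def _as_array(X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
    return X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


@dataclass
class ClassifierConfig:
    """Settings for the desk-scale reference learner (multinomial linear)."""

    seed: int = 0
    C: float = 1.0
    max_iter: int = 2000


class LinearPatchClassifier:
    """Convex, seeded multinomial linear model honouring the contract.

    ``predict_proba`` always returns one column per class in ``classes``
    order, inserting zero columns for classes absent from training; rows sum
    to 1 within 1e-6 and inference is deterministic.
    """

    def __init__(
        self,
        classes: Sequence[str] = CLASSES,
        config: Optional[ClassifierConfig] = None,
    ) -> None:
        self.classes = tuple(classes)
        self.config = config or ClassifierConfig()
        self._model: Optional[LogisticRegression] = None
        self._seen: tuple = ()
        self.metadata: dict = {}

    def fit(
        self,
        X: Union[FeatureMatrix, np.ndarray],
        y: Sequence[str],
        X_val: Optional[Union[FeatureMatrix, np.ndarray]] = None,
        y_val: Optional[Sequence[str]] = None,
    ) -> "LinearPatchClassifier":
        Xa = _as_array(X)
        y = np.asarray(y)
        present = np.unique(y)
        if present.size < 2:
            raise ValueError("training labels contain a single class")
        unknown = set(present) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside the class list: {sorted(unknown)}")
        # features are standardised inside the learner so heterogeneous
        # descriptor scales (e.g. channel means vs histogram frequencies) do
        # not dominate the fit
        self._model = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "logit",
                    LogisticRegression(
                        C=self.config.C,
                        max_iter=self.config.max_iter,
                        random_state=self.config.seed,
                    ),
                ),
            ]
        )
        self._model.fit(Xa, y)
        self._seen = tuple(self._model.classes_)
        self.metadata = {"seed": self.config.seed, "n_train": int(Xa.shape[0])}
        if X_val is not None and y_val is not None:
            self.metadata["val_accuracy"] = float(self.accuracy(X_val, y_val))
        return self

    def predict_proba(self, X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        Xa = _as_array(X)
        raw = self._model.predict_proba(Xa)
        out = np.zeros((Xa.shape[0], len(self.classes)))
        for j, cls in enumerate(self._seen):
            out[:, self.classes.index(cls)] = raw[:, j]
        return out

    def predict(self, X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
        proba = self.predict_proba(X)
        idx = np.argmax(proba, axis=1)  # ties resolve to class order
        return np.asarray([self.classes[i] for i in idx])

    def accuracy(self, X: Union[FeatureMatrix, np.ndarray], y: Sequence[str]) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_patch_classifier(
    X_train: Union[FeatureMatrix, np.ndarray],
    y_train: Sequence[str],
    X_val: Optional[Union[FeatureMatrix, np.ndarray]] = None,
    y_val: Optional[Sequence[str]] = None,
    config: Optional[ClassifierConfig] = None,
    classes: Sequence[str] = CLASSES,
) -> LinearPatchClassifier:
    """Train the reference patch classifier (any contract learner is admissible)."""
    clf = LinearPatchClassifier(classes=classes, config=config)
    return clf.fit(X_train, y_train, X_val, y_val)


@dataclass
class ClusterSelection:
    """Benchmark accuracy, per-cluster accuracies, and the selected set."""

    benchmark_accuracy: float
    per_cluster_accuracy: dict
    selected: frozenset
    fallback_used: bool = False

    def __post_init__(self) -> None:
        self.selected = frozenset(int(k) for k in self.selected)
        if not self.selected:
            raise ValueError("selected cluster set must be non-empty")

    def to_dict(self) -> dict:
        return {
            "benchmark_accuracy": self.benchmark_accuracy,
            "per_cluster_accuracy": {str(k): v for k, v in self.per_cluster_accuracy.items()},
            "selected": sorted(self.selected),
            "fallback_used": self.fallback_used,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClusterSelection":
        return cls(
            benchmark_accuracy=float(d["benchmark_accuracy"]),
            per_cluster_accuracy={int(k): float(v) for k, v in d["per_cluster_accuracy"].items()},
            selected=frozenset(int(k) for k in d["selected"]),
            fallback_used=bool(d.get("fallback_used", False)),
        )


def select_clusters(
    per_cluster: Mapping[int, LinearPatchClassifier],
    benchmark: LinearPatchClassifier,
    X_val: Union[FeatureMatrix, np.ndarray],
    y_val: Sequence[str],
    cluster_ids: Sequence[int],
) -> ClusterSelection:
    """Keep clusters whose validation accuracy strictly beats the benchmark.

    The benchmark accuracy is computed on all validation patches; each
    cluster's accuracy on its own validation patches. Empty validation
    clusters are excluded from candidacy. If no cluster beats the benchmark,
    the single best cluster is selected as a logged fallback.
    """
    Xa = _as_array(X_val)
    y = np.asarray(y_val)
    cids = np.asarray(cluster_ids)
    if Xa.shape[0] != y.shape[0] or y.shape[0] != cids.shape[0]:
        raise ValueError("X_val, y_val and cluster_ids must align")
    bench_acc = benchmark.accuracy(Xa, y)
    per_acc: dict[int, float] = {}
    for k, clf in per_cluster.items():
        m = cids == k
        if not m.any():
            logger.warning("cluster %d has no validation patches; excluded", k)
            continue
        per_acc[int(k)] = clf.accuracy(Xa[m], y[m])
    if not per_acc:
        raise ValueError("no cluster has validation patches")
    selected = {k for k, acc in per_acc.items() if acc > bench_acc}
    fallback = False
    if not selected:
        best = min(per_acc, key=lambda k: (-per_acc[k], k))
        selected = {best}
        fallback = True
        warnings.warn(
            f"no cluster beat the benchmark accuracy {bench_acc:.3f}; "
            f"falling back to the single best cluster {best}"
        )
    return ClusterSelection(bench_acc, per_acc, frozenset(selected), fallback)


@dataclass
class PatientPrediction:
    """Per-class vote counts and the majority-vote category for a patient."""

    patient_id: str
    votes: dict
    mean_proba: dict
    predicted: str
    n_patches_used: int
    fallback_all_patches: bool = False


def predict_patient(
    patient_id: str,
    patch_probas: np.ndarray,
    cluster_ids: Optional[Sequence[int]] = None,
    selection: Optional[ClusterSelection] = None,
    classes: Sequence[str] = CLASSES,
) -> PatientPrediction:
    """Majority vote over a patient's patches in selected clusters.

    Each patch votes its argmax class. Vote ties are broken by the higher
    mean predicted probability among the tied classes, then by class order.
    If no patch falls in a selected cluster, all patches vote (logged
    fallback). With ``selection=None`` every patch votes.
    """
    P = np.asarray(patch_probas, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(classes):
        raise ValueError(f"patch_probas must be n x {len(classes)}")
    if P.shape[0] == 0:
        raise ValueError(f"patient {patient_id} has zero patches")
    fallback = False
    if selection is not None:
        if cluster_ids is None:
            raise ValueError("cluster_ids required when a selection is given")
        cids = np.asarray(cluster_ids)
        mask = np.isin(cids, list(selection.selected))
        if not mask.any():
            fallback = True
            logger.warning(
                "patient %s has no patches in selected clusters; all patches vote",
                patient_id,
            )
            mask = np.ones(P.shape[0], dtype=bool)
    else:
        mask = np.ones(P.shape[0], dtype=bool)
    used = P[mask]
    arg = np.argmax(used, axis=1)
    counts = np.bincount(arg, minlength=len(classes))
    mean_proba = used.mean(axis=0)
    top = counts.max()
    tied = [i for i in range(len(classes)) if counts[i] == top]
    # ties: higher mean predicted probability among tied classes, then class order
    winner = min(tied, key=lambda i: (-mean_proba[i], i))
    return PatientPrediction(
        patient_id=patient_id,
        votes={cls: int(counts[i]) for i, cls in enumerate(classes)},
        mean_proba={cls: float(mean_proba[i]) for i, cls in enumerate(classes)},
        predicted=classes[winner],
        n_patches_used=int(used.shape[0]),
        fallback_all_patches=fallback,
    )


def predictions_to_frame(
    preds: Sequence[PatientPrediction], classes: Sequence[str] = CLASSES
) -> pd.DataFrame:
    columns = (
        ["patient_id", "predicted", "n_patches_used"]
        + [f"votes_{cls}" for cls in classes]
        + [f"mean_proba_{cls}" for cls in classes]
    )
    rows = []
    for p in preds:
        row = {"patient_id": p.patient_id, "predicted": p.predicted,
               "n_patches_used": p.n_patches_used}
        for cls in classes:
            row[f"votes_{cls}"] = p.votes.get(cls, 0)
        for cls in classes:
            row[f"mean_proba_{cls}"] = p.mean_proba.get(cls, 0.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
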