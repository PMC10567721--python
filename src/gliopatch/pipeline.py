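"""End-to-end orchestration of the four-step pipeline.

Patch clustering -> benchmark-relative patch selection -> patch-level
classification -> patient-level majority voting, driven by one configuration
object with a single global seed fanned out to per-stage seeds by fixed
offsets. The feature-tier entry point (`train_on_features`) works on any
FeatureMatrix; the slide-tier entry points (`run_train`, `run_predict`) add
segmentation, tiling, and feature extraction in front of it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import pandas as pd

from .clustering import (
    ClusterModel,
    assign_clusters,
    choose_k,
    fit_kmeans,
    score_k,
)
from .evaluate import EvalReport, make_folds, ovr_report
from .features import (
    BaselineTextureExtractor,
    FeatureExtractor,
    FeatureMatrix,
    extract_features,
    iter_slide_patches,
)
from .patchmodel import (
    CLASSES,
    ClassifierConfig,
    ClusterSelection,
    LinearPatchClassifier,
    PatientPrediction,
    predict_patient,
    predictions_to_frame,
    select_clusters,
    train_patch_classifier,
)
from .slide_io import SlideRecord, segment_tissue, tile_patches

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets fanned out from the single global seed
_SEED_SPLIT = 11
_SEED_SUBSAMPLE = 23
_SEED_CLUSTER = 37


@dataclass
class PipelineConfig:
    """Stage parameters for one training run."""

    seed: int = 0
    k_min: int = 2
    k_max: int = 12
    restarts: int = 10
    cluster_subsample: int = 2000
    fixed_k: Optional[int] = None          # bypass the K scan when set
    patch_size: int = 1024
    min_tissue_fraction: float = 0.5
    downsample: int = 4
    val_fraction_folds: int = 5            # 4:1 split = fold 0 of 5
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    classes: Tuple[str, ...] = CLASSES

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classes"] = list(self.classes)
        return d


@dataclass
class PipelineModel:
    """Everything needed to predict: clustering, selection, classifiers."""

    cluster_model: ClusterModel
    selection: ClusterSelection
    benchmark: LinearPatchClassifier
    per_cluster: dict
    final: LinearPatchClassifier
    config: PipelineConfig
    metrics: dict = field(default_factory=dict)

    @property
    def classes(self) -> Tuple[str, ...]:
        return self.config.classes

    def save(self, directory: Union[str, Path]) -> None:
        """Model bundle: clustering archive + selection JSON + classifiers."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cluster_model.save(directory / "clustering")
        (directory / "selection.json").write_text(json.dumps(self.selection.to_dict()))
        (directory / "config.json").write_text(json.dumps(self.config.to_dict()))
        (directory / "metrics.json").write_text(json.dumps(self.metrics))
        joblib.dump(
            {"benchmark": self.benchmark, "per_cluster": self.per_cluster, "final": self.final},
            directory / "classifiers.joblib",
        )

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "PipelineModel":
        directory = Path(directory)
        cluster_model = ClusterModel.load(directory / "clustering")
        selection = ClusterSelection.from_dict(
            json.loads((directory / "selection.json").read_text())
        )
        cfg_d = json.loads((directory / "config.json").read_text())
        cfg_d["classes"] = tuple(cfg_d["classes"])
        cfg_d["classifier"] = ClassifierConfig(**cfg_d["classifier"])
        config = PipelineConfig(**cfg_d)
        metrics = json.loads((directory / "metrics.json").read_text())
        clfs = joblib.load(directory / "classifiers.joblib")
        return cls(
            cluster_model, selection, clfs["benchmark"], clfs["per_cluster"],
            clfs["final"], config, metrics,
        )


def _patient_split(
    patients: np.ndarray,
    labels: np.ndarray,
    cfg: PipelineConfig,
) -> Tuple[set, set]:
    """Stratified 4:1 patient split (validation = fold 0 of a 5-fold plan)."""
    pid_list = pd.unique(patients)
    pid_labels = pd.Series(labels, index=patients).groupby(level=0).first()
    plan = make_folds(
        pid_list,
        pid_labels.loc[pid_list].to_numpy(),
        n_folds=cfg.val_fraction_folds,
        seed=cfg.seed + _SEED_SPLIT,
    )
    train, val = plan.split(0)
    return set(train), set(val)


def train_on_features(
    fm: FeatureMatrix,
    labels: Sequence[str],
    patients: Sequence[str],
    cfg: Optional[PipelineConfig] = None,
    val_patients: Optional[set] = None,
) -> PipelineModel:
    """Train the full clustering-based model on patch features.

    ``labels``/``patients`` align with the rows of ``fm``. When
    ``val_patients`` is None, a stratified 4:1 patient-level split is drawn
    from the run seed. Clustering is fitted on a seeded subsample of training
    patches (``cfg.cluster_subsample``), scanned over K in
    [cfg.k_min, cfg.k_max] with K chosen by silhouette (Calinski-Harabasz as
    the cross-check), then applied to all patches. Per-cluster classifiers
    and the all-patch benchmark are trained on training patches and compared
    on validation patches; the final classifier is retrained from scratch on
    the union of selected clusters.
    """
    cfg = cfg or PipelineConfig()
    y = np.asarray([str(v) for v in labels])
    pids = np.asarray([str(v) for v in patients])
    if not (fm.n == y.shape[0] == pids.shape[0]):
        raise ValueError("features, labels and patients must align")
    if val_patients is None:
        train_p, val_p = _patient_split(pids, y, cfg)
    else:
        val_p = set(map(str, val_patients))
        train_p = set(pd.unique(pids)) - val_p
    tr = np.isin(pids, list(train_p))
    va = np.isin(pids, list(val_p))
    if not tr.any() or not va.any():
        raise ValueError("both training and validation patients are required")
    X = fm.X

    # --- patch clustering on a seeded training subsample -------------------
    rng = np.random.default_rng(cfg.seed + _SEED_SUBSAMPLE)
    tr_idx = np.flatnonzero(tr)
    n_sub = min(cfg.cluster_subsample, tr_idx.size)
    sub = rng.choice(tr_idx, size=n_sub, replace=False)
    cluster_seed = cfg.seed + _SEED_CLUSTER
    if cfg.fixed_k is not None:
        k_star = cfg.fixed_k
        quality = None
    else:
        quality = score_k(
            X[sub], range(cfg.k_min, cfg.k_max + 1), seed=cluster_seed,
            restarts=cfg.restarts,
        )
        k_star = choose_k(quality)
    cluster_model = fit_kmeans(X[sub], k_star, seed=cluster_seed, restarts=cfg.restarts)
    cluster_model.quality = quality
    cids = assign_clusters(X, cluster_model)
    logger.info("clustering: K=%d on %d subsampled patches", k_star, n_sub)

    # --- benchmark + per-cluster classifiers --------------------------------
    clf_cfg = ClassifierConfig(
        seed=cfg.classifier.seed + cfg.seed,
        C=cfg.classifier.C,
        max_iter=cfg.classifier.max_iter,
    )
    benchmark = train_patch_classifier(
        X[tr], y[tr], X[va], y[va], config=clf_cfg, classes=cfg.classes
    )
    per_cluster: dict[int, LinearPatchClassifier] = {}
    for k in range(k_star):
        m = tr & (cids == k)
        if m.sum() < 2 or np.unique(y[m]).size < 2:
            logger.warning("cluster %d lacks a trainable 2-class sample; skipped", k)
            continue
        per_cluster[k] = train_patch_classifier(
            X[m], y[m], config=clf_cfg, classes=cfg.classes
        )

    # --- benchmark-relative selection on the validation cohort -------------
    selection = select_clusters(per_cluster, benchmark, X[va], y[va], cids[va])
    logger.info(
        "selection: %d/%d clusters beat benchmark accuracy %.3f",
        len(selection.selected), k_star, selection.benchmark_accuracy,
    )

    # --- final classifier on the union of selected clusters ----------------
    sel_tr = tr & np.isin(cids, list(selection.selected))
    if np.unique(y[sel_tr]).size < 2:
        logger.warning("selected clusters lack 2 classes in training; using all patches")
        sel_tr = tr
    final = train_patch_classifier(
        X[sel_tr], y[sel_tr], config=clf_cfg, classes=cfg.classes
    )
    sel_va = va & np.isin(cids, list(selection.selected))
    metrics = {
        "K": int(k_star),
        "n_train_patches": int(tr.sum()),
        "n_val_patches": int(va.sum()),
        "benchmark_val_accuracy": float(benchmark.accuracy(X[va], y[va])),
        "final_val_patch_accuracy": float(final.accuracy(X[sel_va], y[sel_va]))
        if sel_va.any()
        else None,
        "selected_clusters": sorted(selection.selected),
        "train_patients": sorted(train_p),
        "val_patients": sorted(val_p),
    }
    return PipelineModel(cluster_model, selection, benchmark, per_cluster, final, cfg, metrics)


def predict_patients(
    model: PipelineModel,
    fm: FeatureMatrix,
    patients: Sequence[str],
    use_all_patches: bool = False,
) -> list[PatientPrediction]:
    """Patient-level majority-vote predictions for a patch feature matrix.

    With ``use_all_patches=True`` the all-patch benchmark classifier votes on
    every patch (the comparison pipeline); otherwise the final classifier
    votes on patches assigned to selected clusters.
    """
    pids = np.asarray([str(v) for v in patients])
    if fm.n != pids.shape[0]:
        raise ValueError("features and patients must align")
    if fm.dim != model.cluster_model.dim:
        raise ValueError(
            f"feature dimension {fm.dim} does not match the bundle "
            f"({model.cluster_model.dim})"
        )
    clf = model.benchmark if use_all_patches else model.final
    P = clf.predict_proba(fm.X)
    cids = assign_clusters(fm.X, model.cluster_model)
    selection = None if use_all_patches else model.selection
    preds = []
    for pid in pd.unique(pids):
        m = pids == pid
        preds.append(
            predict_patient(
                pid, P[m], cids[m], selection=selection, classes=model.classes
            )
        )
    return preds


def patient_accuracy(
    preds: Sequence[PatientPrediction], truth: dict, classes: Sequence[str] = CLASSES
) -> Tuple[float, float]:
    """(overall accuracy, macro accuracy = unweighted mean per-class recall)."""
    correct: dict[str, list] = {c: [] for c in classes}
    hits = 0
    for p in preds:
        t = truth[p.patient_id]
        ok = p.predicted == t
        hits += ok
        correct[t].append(ok)
    overall = hits / len(preds)
    recalls = [np.mean(v) for v in correct.values() if v]
    return float(overall), float(np.mean(recalls))


# ----------------------------------------------------------------------------
# Slide-tier orchestration
# ----------------------------------------------------------------------------

def extract_cohort_features(
    manifest: pd.DataFrame,
    cfg: PipelineConfig,
    extractor: Optional[FeatureExtractor] = None,
) -> Tuple[FeatureMatrix, pd.DataFrame]:
    """Segment -> tile -> extract over a slide manifest.

    The manifest needs columns slide_id, patient_id, path (and optionally
    label, mpp). Returns the pooled FeatureMatrix and a patch table aligned
    with it (patch_id, slide_id, patient_id, x, y, label).
    """
    extractor = extractor or BaselineTextureExtractor()
    mats: list[FeatureMatrix] = []
    patch_rows: list[dict] = []
    for row in manifest.itertuples(index=False):
        label = getattr(row, "label", None)
        if label is not None and pd.isna(label):
            label = None
        rec = SlideRecord(
            slide_id=str(row.slide_id),
            patient_id=str(row.patient_id),
            image_source=str(row.path),
            mpp=float(getattr(row, "mpp", 0.5)),
            label=None if label is None else str(label),
        )
        image = rec.read()
        mask = segment_tissue(image, downsample=cfg.downsample)
        refs = tile_patches(
            image,
            mask,
            patch_size=cfg.patch_size,
            min_tissue_fraction=cfg.min_tissue_fraction,
            slide_id=rec.slide_id,
            patient_id=rec.patient_id,
            label=rec.label,
        )
        if not refs:
            logger.warning("slide %s produced no tissue patches", rec.slide_id)
            continue
        fm = extract_features(iter_slide_patches(image, refs), extractor)
        mats.append(fm)
        for r in refs:
            patch_rows.append(
                {
                    "patch_id": r.patch_id,
                    "slide_id": r.slide_id,
                    "patient_id": r.patient_id,
                    "x": r.x,
                    "y": r.y,
                    "label": r.label,
                }
            )
        logger.info("slide %s: %d tissue patches", rec.slide_id, len(refs))
    if not mats:
        raise ValueError("no slide yielded tissue patches")
    pooled = FeatureMatrix(
        [pid for m in mats for pid in m.patch_ids],
        np.vstack([m.X for m in mats]),
        extractor.descriptor,
    )
    return pooled, pd.DataFrame(patch_rows)


def run_train(
    manifest: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
    bundle_dir: Optional[Union[str, Path]] = None,
    extractor: Optional[FeatureExtractor] = None,
) -> PipelineModel:
    """Slide-tier training: segment, tile, extract, then train_on_features."""
    cfg = cfg or PipelineConfig()
    if "label" not in manifest.columns or manifest["label"].isna().any():
        raise ValueError("training manifest must have a complete 'label' column")
    fm, patches = extract_cohort_features(manifest, cfg, extractor)
    model = train_on_features(
        fm, patches["label"].to_numpy(), patches["patient_id"].to_numpy(), cfg
    )
    if bundle_dir is not None:
        model.save(bundle_dir)
    return model


def run_predict(
    model: PipelineModel,
    manifest: pd.DataFrame,
    out_csv: Optional[Union[str, Path]] = None,
    extractor: Optional[FeatureExtractor] = None,
) -> pd.DataFrame:
    """Slide-tier prediction over a (possibly unlabeled) manifest."""
    if manifest.empty:
        logger.warning("empty manifest; writing header-only predictions")
        df = predictions_to_frame([], model.classes)
    else:
        fm, patches = extract_cohort_features(manifest, model.config, extractor)
        preds = predict_patients(model, fm, patches["patient_id"].to_numpy())
        df = predictions_to_frame(preds, model.classes)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def run_eval(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    classes: Sequence[str] = CLASSES,
) -> EvalReport:
    """Score patient predictions (with per-class mean probabilities) against truth.

    ``predictions`` is the run_predict frame; ``truth`` needs patient_id and
    label columns. Unmatched patient ids raise an error listing them.
    """
    t = truth.set_index(truth["patient_id"].astype(str))["label"]
    pids = predictions["patient_id"].astype(str)
    missing = sorted(set(pids) - set(t.index))
    if missing:
        raise ValueError(f"no truth labels for patients: {missing}")
    y = t.loc[pids].to_numpy()
    proba_cols = [f"mean_proba_{c}" for c in classes]
    P = predictions[proba_cols].to_numpy(dtype=float)
    P = P / P.sum(axis=1, keepdims=True)  # renormalise vote-weighted means
    return ovr_report(y, P, classes)
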