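"""Patch-feature clustering with automatic choice of the cluster number K.

K-means (Lloyd's algorithm, k-means++ seeding, best of several restarts) is
scanned over a range of K (2..12 by default). The mean silhouette coefficient
is the primary model-selection statistic; the Calinski-Harabasz index is a
cross-check, and a warning is logged when the two disagree on the argmax.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = range(2, 13)
SILHOUETTE_SUBSAMPLE = 20_000


def _as_array(X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
    return X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


@dataclass
class ClusterModel:
    """A fitted K-means model plus the per-K quality table of the scan."""

    K: int
    centroids: np.ndarray
    seed: int
    inertia: float
    quality: Optional[pd.DataFrame] = None  # columns: K, silhouette, calinski_harabasz

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if not np.isfinite(self.centroids).all():
            raise ValueError("centroids must be finite")

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def save(self, directory: Union[str, Path]) -> None:
        """JSON header + binary centroid block (+ quality CSV if present)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "model.json").write_text(
            json.dumps({"K": self.K, "seed": self.seed, "inertia": self.inertia})
        )
        np.save(directory / "centroids.npy", self.centroids)
        if self.quality is not None:
            self.quality.to_csv(directory / "quality.csv", index=False)

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "ClusterModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        centroids = np.load(directory / "centroids.npy")
        quality = None
        qpath = directory / "quality.csv"
        if qpath.exists():
            quality = pd.read_csv(qpath)
        return cls(int(meta["K"]), centroids, int(meta["seed"]), float(meta["inertia"]), quality)


def fit_kmeans(
    X: Union[FeatureMatrix, np.ndarray],
    K: int,
    seed: int = 0,
    restarts: int = 10,
) -> ClusterModel:
    """Lloyd's K-means, k-means++ seeding, best of ``restarts`` by inertia.

    Deterministic given ``seed``. Raises for K < 1 or fewer points than
    clusters. Empty clusters are re-seeded from far points internally.
    """
    arr = _as_array(X)
    if K < 1:
        raise ValueError("K must be >= 1")
    if arr.shape[0] < K:
        raise ValueError(f"cannot fit {K} clusters on {arr.shape[0]} points")
    km = KMeans(n_clusters=K, init="k-means++", n_init=restarts, random_state=seed)
    km.fit(arr)
    return ClusterModel(K=K, centroids=km.cluster_centers_, seed=seed, inertia=float(km.inertia_))


def silhouette_mean(
    X: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    subsample: int = SILHOUETTE_SUBSAMPLE,
) -> float:
    """Mean silhouette over all points; singleton clusters contribute 0.

    Degenerate partitions where every cluster is a singleton (or only one
    cluster exists) score 0 by convention. Datasets beyond ``subsample``
    points are scored on a seeded subsample.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    n_labels = len(np.unique(labels))
    if n_labels < 2 or n_labels >= n:
        return 0.0
    if n > subsample:
        return float(
            silhouette_score(X, labels, sample_size=subsample, random_state=seed)
        )
    return float(silhouette_score(X, labels))


def _calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    n = X.shape[0]
    k = len(np.unique(labels))
    if k < 2:
        return 0.0
    if k >= n:  # zero within-cluster dispersion
        return float("inf")
    return float(calinski_harabasz_score(X, labels))


def score_k(
    X: Union[FeatureMatrix, np.ndarray],
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    seed: int = 0,
    restarts: int = 10,
    subsample: int = SILHOUETTE_SUBSAMPLE,
) -> pd.DataFrame:
    """Fit each K in the range and tabulate (silhouette, Calinski-Harabasz)."""
    arr = _as_array(X)
    rows = []
    for K in k_range:
        if K > arr.shape[0]:
            raise ValueError(f"K={K} exceeds the number of points ({arr.shape[0]})")
        model = fit_kmeans(arr, K, seed=seed, restarts=restarts)
        labels = assign_clusters(arr, model)
        rows.append(
            {
                "K": K,
                "silhouette": silhouette_mean(arr, labels, seed=seed, subsample=subsample),
                "calinski_harabasz": _calinski_harabasz(arr, labels),
            }
        )
    if not rows:
        raise ValueError("empty k_range")
    return pd.DataFrame(rows)


def choose_k(quality: Union[pd.DataFrame, Mapping[int, tuple]]) -> int:
    """argmax of silhouette; ties broken by higher CH, then smaller K.

    Logs a warning when the Calinski-Harabasz argmax disagrees with the
    silhouette argmax.
    """
    if isinstance(quality, Mapping):
        df = pd.DataFrame(
            [
                {"K": k, "silhouette": v[0], "calinski_harabasz": v[1]}
                for k, v in quality.items()
            ]
        )
    else:
        df = quality
    if df.empty:
        raise ValueError("empty quality table")
    df = df.sort_values(
        ["silhouette", "calinski_harabasz", "K"], ascending=[False, False, True]
    )
    k_star = int(df.iloc[0]["K"])
    ch_best = int(df.sort_values(["calinski_harabasz", "K"], ascending=[False, True]).iloc[0]["K"])
    if ch_best != k_star:
        logger.warning(
            "Calinski-Harabasz argmax (K=%d) disagrees with silhouette argmax (K=%d)",
            ch_best,
            k_star,
        )
    return k_star


def assign_clusters(
    X: Union[FeatureMatrix, np.ndarray], model: ClusterModel
) -> np.ndarray:
    """Nearest-centroid assignment (Euclidean); ties go to the lowest id."""
    arr = _as_array(X)
    if arr.shape[1] != model.dim:
        raise ValueError(
            f"feature dimension {arr.shape[1]} does not match model dimension {model.dim}"
        )
    d = cdist(arr, model.centroids)
    return np.argmin(d, axis=1)  # argmin takes the first index on ties
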