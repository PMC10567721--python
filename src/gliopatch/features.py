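"""Patch feature extraction behind a pluggable contract.

Patches are resized to 256x256 and mapped to fixed-length vectors. Any pure
function of pixel content with a declared dimensionality satisfies the
contract (a trained CNN embedding is one admissible implementation); the
package ships a deterministic hand-crafted texture extractor so the
clustering and selection stages are testable at desk scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

logger = logging.getLogger(__name__)

PATCH_INPUT_SIZE = 256


class FeatureExtractor(Protocol):
    """Contract: a pure, fixed-dimension map from patch pixels to floats."""

    dim: int
    descriptor: str

    def transform(self, patch: np.ndarray) -> np.ndarray: ...


@dataclass
class FeatureMatrix:
    """Patch-id-indexed feature vectors (rows align with patch_ids)."""

    patch_ids: list[str]
    X: np.ndarray
    extractor_descriptor: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.patch_ids) != self.X.shape[0]:
            raise ValueError("patch_ids and X row counts differ")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def save(self, path: Union[str, Path]) -> None:
        """Columnar binary container (.npz) with an embedded JSON header."""
        header = json.dumps({"extractor": self.extractor_descriptor, "dim": self.dim})
        np.savez(
            path,
            X=self.X,
            patch_ids=np.asarray(self.patch_ids, dtype=object),
            header=np.asarray(header),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "FeatureMatrix":
        with np.load(path, allow_pickle=True) as z:
            header = json.loads(str(z["header"]))
            return cls(
                patch_ids=[str(p) for p in z["patch_ids"]],
                X=z["X"],
                extractor_descriptor=header.get("extractor", ""),
            )

    def to_csv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(self.X, index=pd.Index(self.patch_ids, name="patch_id"))
        df.to_csv(path)


def resize_patch(patch: np.ndarray, size: int = PATCH_INPUT_SIZE) -> np.ndarray:
    """Bilinear resize of a square patch to size x size, channels preserved.

    Anti-aliased when downsampling, so block means are preserved. Inputs
    already at the target size are returned unchanged.
    """
    patch = np.asarray(patch)
    if patch.shape[0] != patch.shape[1]:
        raise ValueError(f"expected a square patch, got shape {patch.shape[:2]}")
    if patch.shape[0] == size:
        return patch
    out_shape = (size, size) + patch.shape[2:]
    anti_alias = patch.shape[0] > size
    out = sk_resize(
        patch.astype(float), out_shape, order=1, anti_aliasing=anti_alias, preserve_range=True
    )
    if np.issubdtype(patch.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(patch.dtype)
    return out


def _as_float255(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.max(initial=0.0) <= 1.0 and not np.issubdtype(np.asarray(img).dtype, np.integer):
        arr = arr * 255.0
    return arr


class BaselineTextureExtractor:
    """Deterministic hand-crafted descriptor (D = 38).

    Per channel: mean and variance (6), an 8-bin intensity histogram
    normalised to frequencies (24); then mean/variance of the gradient
    magnitude of the grey image on a fixed 2x2 spatial grid (8). Intensities
    are on the 0..255 scale, so a pure-white patch yields channel means of
    255, zero variances, all histogram mass in the last bin, and zero
    gradient statistics.
    """

    dim = 38
    descriptor = "baseline-texture-v1 (chan mean/var, 8-bin hists, 2x2 gradient stats)"

    def transform(self, patch: np.ndarray) -> np.ndarray:
        arr = _as_float255(patch)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise ValueError(f"expected an RGB patch, got shape {np.asarray(patch).shape}")
        feats: list[float] = []
        for ch in range(3):
            band = arr[..., ch]
            feats.append(band.mean())
            feats.append(band.var())
        npix = arr.shape[0] * arr.shape[1]
        for ch in range(3):
            counts, _ = np.histogram(arr[..., ch], bins=8, range=(0.0, 256.0))
            feats.extend(counts / npix)
        grey = arr.mean(axis=-1)
        gy, gx = np.gradient(grey)
        gm = np.hypot(gx, gy)
        h2, w2 = gm.shape[0] // 2, gm.shape[1] // 2
        for blk in (gm[:h2, :w2], gm[:h2, w2:], gm[h2:, :w2], gm[h2:, w2:]):
            feats.append(blk.mean() if blk.size else 0.0)
            feats.append(blk.var() if blk.size else 0.0)
        return np.asarray(feats, dtype=float)


def extract_features(
    patches: Iterable[Tuple[str, np.ndarray]],
    extractor: FeatureExtractor,
    resize: bool = True,
) -> FeatureMatrix:
    """Map (patch_id, raster) pairs to a FeatureMatrix, order preserved.

    A patch whose pixels cannot be read or transformed is skipped with a
    warning; its row is omitted rather than filled.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for patch_id, img in patches:
        try:
            arr = resize_patch(img) if resize else np.asarray(img)
            vec = np.asarray(extractor.transform(arr), dtype=float)
        except Exception as exc:  # noqa: BLE001 - contract: skip + warn
            warnings.warn(f"skipping patch {patch_id}: {exc}")
            continue
        if vec.shape != (extractor.dim,):
            raise ValueError(
                f"extractor returned shape {vec.shape}, expected ({extractor.dim},)"
            )
        ids.append(patch_id)
        rows.append(vec)
    X = np.vstack(rows) if rows else np.empty((0, extractor.dim))
    return FeatureMatrix(ids, X, extractor.descriptor)


def iter_slide_patches(image: np.ndarray, refs: Sequence) -> Iterable[Tuple[str, np.ndarray]]:
    """Yield (patch_id, crop) pairs for PatchRefs over one slide image."""
    for ref in refs:
        yield ref.patch_id, image[ref.y : ref.y + ref.size, ref.x : ref.x + ref.size]
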