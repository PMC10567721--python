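"""Slide reading, tissue segmentation, and patch tiling.

Tissue is segmented at a low magnification (the 5x level of a 20x scan, i.e.
a 4x downsample of level 0) by converting RGB to CIE L*a*b* and thresholding
the chroma magnitude sqrt(a*^2 + b*^2) with Otsu's method: H&E-stained tissue
is chromatic while the glass background is near-achromatic white, so chroma
separates the two regardless of illumination level. Retained patches sit on a
non-overlapping grid anchored at the image origin, in level-0 pixel
coordinates (0-based, half-open intervals).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import imageio.v3 as iio
from skimage import color as skcolor
from skimage.transform import resize as sk_resize

logger = logging.getLogger(__name__)

GLIOMA_CLASSES = ("A2", "A3", "A4", "O2", "O3", "GBM")


class DegenerateHistogramError(ValueError):
    """All histogram mass sits in a single bin; no threshold splits it."""


@dataclass
class SlideRecord:
    """One whole-slide image with its metadata (one slide per patient)."""

    slide_id: str
    patient_id: str
    image_source: Union[str, Path, np.ndarray]
    mpp: float = 0.5
    label: Optional[str] = None
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError(f"mpp must be positive, got {self.mpp}")
        if self.label is not None and self.label not in GLIOMA_CLASSES:
            raise ValueError(f"unknown label {self.label!r}")

    def read(self) -> np.ndarray:
        """Return the level-0 RGB raster as a HxWx3 uint8 array."""
        if isinstance(self.image_source, np.ndarray):
            return self.image_source
        img = iio.imread(self.image_source)
        if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
            img = img[..., :3]
        return img


@dataclass
class TissueMask:
    """Binary tissue raster at a stated downsample of the level-0 image."""

    mask: np.ndarray
    downsample: int
    threshold_used: float

    def __post_init__(self) -> None:
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class PatchRef:
    """A patch on the level-0 grid: origin (x, y), half-open [x, x+size)."""

    slide_id: str
    x: int
    y: int
    size: int = 1024
    tissue_fraction: float = 1.0
    label: Optional[str] = None
    patient_id: Optional[str] = None
    cluster_id: Optional[int] = None

    @property
    def patch_id(self) -> str:
        return f"{self.slide_id}:{self.x}:{self.y}"


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB raster to CIE L*a*b* (D65, sRGB transfer).

    L* lies in [0, 100]; a*/b* are signed. Raises ``ValueError`` for inputs
    without exactly three channels.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an RGB image with 3 channels, got shape {image.shape}")
    return skcolor.rgb2lab(image)


def otsu_threshold(histogram: Sequence[float]) -> int:
    """Smallest bin index t maximizing between-class variance of [0..t] vs [t+1..].

    Operates directly on a histogram of counts. Raises
    ``DegenerateHistogramError`` when every count sits in one bin (no split
    has positive mass on both sides) and ``ValueError`` for an empty histogram.
    """
    h = np.asarray(histogram, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram has no mass")
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("all histogram mass in a single bin")
    if np.allclose(h, np.rint(h)):
        # exact integer arithmetic: near-ties in between-class variance are
        # resolved deterministically toward the smallest threshold
        counts = [int(v) for v in np.rint(h)]
        N = sum(counts)
        S = sum(i * c for i, c in enumerate(counts))
        best_t, best_num, best_den = None, -1, 1
        w0 = 0
        s0 = 0
        for t, c in enumerate(counts):
            w0 += c
            s0 += t * c
            if w0 == 0 or w0 == N:
                continue
            num = (S * w0 - N * s0) ** 2   # proportional to between-class variance
            den = w0 * (N - w0)
            if num * best_den > best_num * den:  # strict: keeps the smallest t
                best_t, best_num, best_den = t, num, den
        return int(best_t)
    p = h / total
    bins = np.arange(h.size)
    omega = np.cumsum(p)                 # class-0 mass for split at t
    mu = np.cumsum(p * bins)             # class-0 first moment
    mu_total = mu[-1]
    valid = (omega > 0) & (omega < 1)
    sigma_b = np.full(h.size, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        sb = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[valid] = sb[valid]
    # argmax returns the first (smallest) index on ties
    return int(np.argmax(sigma_b))


def chroma(lab: np.ndarray) -> np.ndarray:
    """Chroma magnitude sqrt(a*^2 + b*^2) of a Lab raster."""
    return np.hypot(lab[..., 1], lab[..., 2])


def segment_tissue(
    slide: Union[SlideRecord, np.ndarray],
    downsample: int = 4,
    n_bins: int = 256,
) -> TissueMask:
    """Segment tissue on a downsampled slide via Otsu on Lab chroma.

    ``downsample=4`` takes a 20x scan to the 5x level. A degenerate chroma
    histogram (e.g. a pure-white slide) yields an empty mask with a warning
    rather than an error.
    """
    image = slide.read() if isinstance(slide, SlideRecord) else np.asarray(slide)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("segment_tissue expects an RGB image")
    if downsample > 1:
        h = max(1, image.shape[0] // downsample)
        w = max(1, image.shape[1] // downsample)
        low = sk_resize(image, (h, w), order=1, anti_aliasing=True, preserve_range=True)
    else:
        low = image.astype(float)
    c = chroma(rgb_to_lab(low.astype(np.uint8)))
    cmax = float(c.max())
    if cmax <= 0:
        warnings.warn("chroma is zero everywhere; returning empty tissue mask")
        return TissueMask(np.zeros(c.shape, dtype=bool), downsample, float("nan"))
    counts, edges = np.histogram(c, bins=n_bins, range=(0.0, cmax))
    try:
        t = otsu_threshold(counts)
    except DegenerateHistogramError:
        warnings.warn("degenerate chroma histogram; returning empty tissue mask")
        return TissueMask(np.zeros(c.shape, dtype=bool), downsample, float("nan"))
    threshold = float(edges[t + 1])  # upper edge of bin t: split [0..t] vs rest
    return TissueMask(c > threshold, downsample, threshold)


def tile_patches(
    slide: Union[SlideRecord, np.ndarray, tuple],
    mask: TissueMask,
    patch_size: int = 1024,
    min_tissue_fraction: float = 0.5,
    label: Optional[str] = None,
    slide_id: Optional[str] = None,
    patient_id: Optional[str] = None,
) -> list[PatchRef]:
    """Tile the level-0 extent into a non-overlapping grid of tissue patches.

    A patch is retained iff the fraction of mask pixels inside its footprint
    is >= ``min_tissue_fraction``. Patches are returned in row-major order.
    ``slide`` may be a SlideRecord, an image array, or an (H, W) shape tuple.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if isinstance(slide, SlideRecord):
        img = slide.read()
        shape = img.shape[:2]
        slide_id = slide_id or slide.slide_id
        patient_id = patient_id or slide.patient_id
        label = label if label is not None else slide.label
    elif isinstance(slide, np.ndarray):
        shape = slide.shape[:2]
    else:
        shape = tuple(slide)[:2]
    slide_id = slide_id or "slide"
    H, W = shape
    d = mask.downsample
    refs: list[PatchRef] = []
    for row in range(H // patch_size):
        y = row * patch_size
        y0, y1 = y // d, -(-(y + patch_size) // d)  # ceil division
        for col in range(W // patch_size):
            x = col * patch_size
            x0, x1 = x // d, -(-(x + patch_size) // d)
            footprint = mask.mask[y0:y1, x0:x1]
            frac = float(footprint.mean()) if footprint.size else 0.0
            if frac >= min_tissue_fraction:
                refs.append(
                    PatchRef(
                        slide_id=slide_id,
                        x=x,
                        y=y,
                        size=patch_size,
                        tissue_fraction=frac,
                        label=label,
                        patient_id=patient_id,
                    )
                )
    return refs


def crop_patch(image: np.ndarray, ref: PatchRef) -> np.ndarray:
    return image[ref.y : ref.y + ref.size, ref.x : ref.x + ref.size]


# ----------------------------------------------------------------------------
# Manifest / mask I/O
# ----------------------------------------------------------------------------

MANIFEST_COLUMNS = ["slide_id", "patient_id", "x", "y", "size", "tissue_fraction", "label"]


def patches_to_frame(refs: Sequence[PatchRef]) -> pd.DataFrame:
    rows = [
        {
            "slide_id": r.slide_id,
            "patient_id": r.patient_id,
            "x": r.x,
            "y": r.y,
            "size": r.size,
            "tissue_fraction": r.tissue_fraction,
            "label": r.label,
        }
        for r in refs
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_patch_manifest(refs: Sequence[PatchRef], path: Union[str, Path]) -> None:
    patches_to_frame(refs).to_csv(path, index=False)


def read_patch_manifest(path: Union[str, Path]) -> list[PatchRef]:
    df = pd.read_csv(path)
    refs = []
    for row in df.itertuples(index=False):
        label = None if pd.isna(row.label) else str(row.label)
        pid = None if pd.isna(row.patient_id) else str(row.patient_id)
        refs.append(
            PatchRef(
                slide_id=str(row.slide_id),
                x=int(row.x),
                y=int(row.y),
                size=int(row.size),
                tissue_fraction=float(row.tissue_fraction),
                label=label,
                patient_id=pid,
            )
        )
    return refs


def write_tissue_mask(mask: TissueMask, png_path: Union[str, Path]) -> None:
    """Write the mask as PNG plus a JSON sidecar (downsample, threshold)."""
    png_path = Path(png_path)
    iio.imwrite(png_path, (mask.mask.astype(np.uint8) * 255))
    sidecar = png_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"downsample": mask.downsample, "threshold_used": mask.threshold_used})
    )


def read_tissue_mask(png_path: Union[str, Path]) -> TissueMask:
    png_path = Path(png_path)
    raster = iio.imread(png_path) > 0
    meta = json.loads(png_path.with_suffix(".json").read_text())
    return TissueMask(raster, int(meta["downsample"]), float(meta["threshold_used"]))
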