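"""Ground-truth-bearing synthetic data for the whole pipeline.

Two tiers:

* **Feature tier** — patch feature vectors drawn from planted Gaussian
  pattern clusters. Each slide has a class label; each patch draws a pattern
  from its class's mixture row and then features from that pattern's
  Gaussian. *Informative* patterns have class-dependent means (so a
  classifier restricted to that pattern's patches can recover the class);
  uninformative patterns are class-independent. This emulates a cohort in
  which only some morphologic patterns carry diagnostic signal.

* **Image tier** — composite texture "slides": a white canvas with a
  contiguous tissue region tiled by chromatic textured blocks (oriented
  sinusoid gratings, one pattern archetype per block, with class-coded
  parameter shifts for informative patterns), plus the true tissue map and
  per-block pattern ids.

Defaults follow the study conditions at desk scale: 6 classes, 9 patterns of
which 3 are informative, 20 slides per class, 64 patches per slide, pattern
separation 8x the within-pattern spread, class-emission separation 2x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import imageio.v3 as iio
from skimage import color as skcolor

from .features import FeatureMatrix
from .patchmodel import CLASSES


def default_mixture(
    n_classes: int = 6,
    n_patterns: int = 9,
    n_informative: int = 3,
    home_weight: float = 0.4,
    spill_weight: float = 0.05,
) -> np.ndarray:
    """Class x pattern mixture with informative patterns concentrated per class.

    Class c's "home" informative pattern is c mod n_informative (so classes
    sharing a home pattern form hard pairs separable only through the
    class-coded emission); other informative patterns get a small spill
    weight and the remaining mass is uniform over uninformative patterns.
    """
    if n_informative > n_patterns:
        raise ValueError("n_informative cannot exceed n_patterns")
    M = np.zeros((n_classes, n_patterns))
    n_uninf = n_patterns - n_informative
    if n_informative == 0:
        M[:] = 1.0 / n_patterns
        return M
    for c in range(n_classes):
        home = c % n_informative
        M[c, home] = home_weight
        for j in range(n_informative):
            if j != home:
                M[c, j] = spill_weight
        rest = 1.0 - M[c, :n_informative].sum()
        if n_uninf:
            M[c, n_informative:] = rest / n_uninf
        else:
            M[c, :n_informative] *= 1.0 / M[c, :n_informative].sum()
    return M


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark."""

    n_classes: int = 6
    n_patterns: int = 9
    n_informative: int = 3
    feature_dim: int = 16
    separation: float = 8.0        # pattern-centroid distance / within-pattern sd
    class_separation: float = 2.0  # class-emission shift inside informative patterns
    slides_per_class: int = 20
    patches_per_slide: int = 64
    patch_size: int = 256
    seed: int = 0
    mixture: Optional[np.ndarray] = None
    classes: Tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        if self.mixture is None:
            self.mixture = default_mixture(
                self.n_classes, self.n_patterns, self.n_informative
            )
        self.mixture = np.asarray(self.mixture, dtype=float)
        if self.mixture.shape != (self.n_classes, self.n_patterns):
            raise ValueError("mixture must be n_classes x n_patterns")
        if np.any(np.abs(self.mixture.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("mixture rows must sum to 1")
        if len(self.classes) < self.n_classes:
            raise ValueError("not enough class names")

    @property
    def informative_patterns(self) -> frozenset:
        return frozenset(range(self.n_informative))


def _orthogonal_directions(rng: np.random.Generator, dim: int, k: int) -> np.ndarray:
    """k mutually orthogonal unit vectors in R^dim (requires k <= dim)."""
    if k > dim:
        raise ValueError(f"need feature_dim >= {k} for {k} separated centroids")
    G = rng.standard_normal((dim, k))
    Q, _ = np.linalg.qr(G)
    return Q[:, :k].T


def _pattern_geometry(cfg: SyntheticConfig, rng: np.random.Generator):
    """Pattern centroids (pairwise distance = separation x unit sd) and
    per-(pattern, class) emission offsets for informative patterns."""
    dirs = _orthogonal_directions(rng, cfg.feature_dim, cfg.n_patterns)
    centroids = dirs * (cfg.separation / np.sqrt(2.0))
    offsets = np.zeros((cfg.n_patterns, cfg.n_classes, cfg.feature_dim))
    for p in range(cfg.n_informative):
        raw = rng.standard_normal((cfg.n_classes, cfg.feature_dim))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        offsets[p] = raw * cfg.class_separation
    return centroids, offsets


def gen_feature_dataset(
    cfg: SyntheticConfig,
) -> Tuple[FeatureMatrix, pd.DataFrame]:
    """Feature-tier benchmark: features plus per-patch ground truth.

    Returns the FeatureMatrix and a truth table aligned row-for-row with it,
    with columns patch_id, patient_id, label, pattern. Fully determined by
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    centroids, offsets = _pattern_geometry(cfg, rng)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    truth: list[dict] = []
    for c in range(cfg.n_classes):
        label = cfg.classes[c]
        for s in range(cfg.slides_per_class):
            pid = f"{label}_{s:03d}"
            patterns = rng.choice(cfg.n_patterns, size=cfg.patches_per_slide, p=cfg.mixture[c])
            noise = rng.standard_normal((cfg.patches_per_slide, cfg.feature_dim))
            for i, p in enumerate(patterns):
                x = centroids[p] + offsets[p, c] + noise[i]
                patch_id = f"{pid}:{i:04d}"
                ids.append(patch_id)
                rows.append(x)
                truth.append(
                    {"patch_id": patch_id, "patient_id": pid, "label": label, "pattern": int(p)}
                )
    fm = FeatureMatrix(ids, np.vstack(rows), f"synthetic-features(seed={cfg.seed})")
    return fm, pd.DataFrame(truth)


def gen_blobs(
    n: int,
    k: int,
    dim: int = 16,
    separation: float = 8.0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """n points from k planted isotropic Gaussian clusters (unit sd).

    Centroids sit at pairwise distance ``separation`` (in within-sd units);
    cluster sizes are as equal as possible. Returns (X, planted labels).
    """
    rng = np.random.default_rng(seed)
    dirs = _orthogonal_directions(rng, dim, k)
    centroids = dirs * (separation / np.sqrt(2.0))
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    X = np.vstack(
        [centroids[j] + rng.standard_normal((sizes[j], dim)) for j in range(k)]
    )
    labels = np.repeat(np.arange(k), sizes)
    return X, labels


# ----------------------------------------------------------------------------
# Image tier
# ----------------------------------------------------------------------------

@dataclass
class SlideTruth:
    """Ground truth for a generated slide."""

    label: str
    tissue_grid: np.ndarray    # gh x gw bool, True where a block is tissue
    pattern_grid: np.ndarray   # gh x gw int, pattern id or -1 for background
    block_size: int

    @property
    def n_tissue_blocks(self) -> int:
        return int(self.tissue_grid.sum())

    def tissue_mask(self) -> np.ndarray:
        """Full-resolution boolean tissue map."""
        return np.kron(self.tissue_grid, np.ones((self.block_size, self.block_size), bool))


def _pattern_texture(
    shape: Tuple[int, int],
    pattern: int,
    n_patterns: int,
    class_idx: int,
    informative: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Chromatic oriented-grating texture for one block, values in [0, 1].

    The base hue/orientation/frequency encode the pattern archetype; for
    informative patterns the hue and grating frequency carry a small
    class-coded shift.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.pi * pattern / n_patterns
    freq = (2.0 + (pattern % 3)) / 32.0  # wavelength 10-16 px
    hue = (0.78 + pattern / n_patterns) % 1.0  # start in H&E pink/purple range
    sat, val = 0.5, 0.82
    if informative:
        hue = (hue + 0.02 * (class_idx - 2.5)) % 1.0
        freq *= 1.0 + 0.06 * class_idx
        sat += 0.015 * (class_idx - 2.5)
    grating = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)))
    v = np.clip(val + 0.13 * grating + rng.normal(0.0, 0.01, shape), 0.55, 0.97)
    hsv = np.stack([np.full(shape, hue), np.full(shape, sat), v], axis=-1)
    return skcolor.hsv2rgb(hsv)


def gen_slide(
    cfg: SyntheticConfig,
    label: str,
    seed: int = 0,
) -> Tuple[np.ndarray, SlideTruth]:
    """One composite texture slide: white background, contiguous tissue region.

    The canvas is a (g+2) x (g+2) grid of ``patch_size`` blocks whose interior
    g x g blocks (g = ceil(sqrt(patches_per_slide))) are tissue, truncated to
    ``patches_per_slide`` blocks in row-major order; each tissue block is one
    pattern archetype drawn from the label's mixture row. Deterministic given
    (label, seed).
    """
    if label not in cfg.classes[: cfg.n_classes]:
        raise ValueError(f"unknown class label {label!r}")
    c = cfg.classes.index(label)
    rng = np.random.default_rng(seed)
    g = int(np.ceil(np.sqrt(cfg.patches_per_slide)))
    gh = gw = g + 2
    bs = cfg.patch_size
    if gh * bs > 32768:
        raise ValueError("patch grid larger than the supported canvas")
    canvas = np.ones((gh * bs, gw * bs, 3))
    tissue_grid = np.zeros((gh, gw), dtype=bool)
    pattern_grid = np.full((gh, gw), -1, dtype=int)
    placed = 0
    for r in range(1, g + 1):
        for col in range(1, g + 1):
            if placed >= cfg.patches_per_slide:
                break
            p = int(rng.choice(cfg.n_patterns, p=cfg.mixture[c]))
            tex = _pattern_texture(
                (bs, bs), p, cfg.n_patterns, c, p < cfg.n_informative, rng
            )
            canvas[r * bs : (r + 1) * bs, col * bs : (col + 1) * bs] = tex
            tissue_grid[r, col] = True
            pattern_grid[r, col] = p
            placed += 1
    img = np.clip(np.rint(canvas * 255), 0, 255).astype(np.uint8)
    return img, SlideTruth(label, tissue_grid, pattern_grid, bs)


def gen_slide_cohort(
    cfg: SyntheticConfig,
    out_dir: Union[str, Path],
    slides_per_class: Optional[int] = None,
) -> pd.DataFrame:
    """Write a cohort of PNG slides plus a manifest and truth tables.

    Returns the slide manifest (slide_id, patient_id, path, mpp, label).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spc = cfg.slides_per_class if slides_per_class is None else slides_per_class
    rows = []
    truth_rows = []
    for c in range(cfg.n_classes):
        label = cfg.classes[c]
        for s in range(spc):
            sid = f"{label}_{s:03d}"
            img, truth = gen_slide(cfg, label, seed=cfg.seed * 100_003 + c * 1000 + s)
            path = out_dir / f"{sid}.png"
            iio.imwrite(path, img)
            rows.append(
                {"slide_id": sid, "patient_id": sid, "path": str(path), "mpp": 0.5,
                 "label": label}
            )
            gh, gw = truth.pattern_grid.shape
            for r in range(gh):
                for col in range(gw):
                    if truth.tissue_grid[r, col]:
                        truth_rows.append(
                            {"slide_id": sid, "row": r, "col": col,
                             "x": col * truth.block_size, "y": r * truth.block_size,
                             "pattern": int(truth.pattern_grid[r, col])}
                        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth_blocks.csv", index=False)
    return manifest
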