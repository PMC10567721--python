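"""Tissue segmentation and patch tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliopatch import (
    SyntheticConfig,
    gen_slide,
    otsu_threshold,
    rgb_to_lab,
    segment_tissue,
    tile_patches,
)
from gliopatch.slide_io import (
    DegenerateHistogramError,
    PatchRef,
    TissueMask,
    read_patch_manifest,
    write_patch_manifest,
)

from conftest import otsu_oracle


def _lab_reference_gray(v: int) -> float:
    """Hand-evaluated sRGB -> XYZ -> L* for a neutral gray level."""
    s = v / 255.0
    lin = ((s + 0.055) / 1.055) ** 2.4 if s > 0.04045 else s / 12.92
    y = lin  # neutral gray: Y equals the linearized value (D65 Yn = 1)
    f = y ** (1 / 3) if y > 0.008856 else 7.787 * y + 16 / 116
    return 116 * f - 16


class TestRgbToLab:
    def test_white_point(self):
        lab = rgb_to_lab(np.full((3, 3, 3), 255, dtype=np.uint8))
        assert np.allclose(lab[..., 0], 100.0, atol=0.01)
        assert np.all(np.abs(lab[..., 1:]) < 0.5)

    def test_black(self):
        lab = rgb_to_lab(np.zeros((2, 2, 3), dtype=np.uint8))
        assert np.allclose(lab, 0.0, atol=1e-6)

    def test_mid_gray_matches_reference_formulas(self):
        lab = rgb_to_lab(np.full((1, 1, 3), 119, dtype=np.uint8))
        expected = _lab_reference_gray(119)
        assert abs(expected - 50.0) < 1.0  # sanity on the oracle itself
        assert abs(lab[0, 0, 0] - expected) < 1e-3
        assert abs(lab[0, 0, 0] - 50.0) < 1.0

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            rgb_to_lab(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            rgb_to_lab(np.zeros((4, 4, 4)))


class TestOtsu:
    def test_two_delta_histogram(self):
        h = np.zeros(256)
        h[0] = 50
        h[255] = 50
        t = otsu_threshold(h)
        assert 0 <= t < 255
        assert t == otsu_oracle(h)

    def test_matches_exhaustive_search_on_random_histograms(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            h = rng.integers(0, 50, size=256)
            if h.sum() == 0 or (h > 0).sum() < 2:
                continue
            assert otsu_threshold(h) == otsu_oracle(h)

    def test_bimodal_gaussian_split_between_modes(self):
        rng = np.random.default_rng(3)
        samples = np.concatenate(
            [rng.normal(60, 10, 5000), rng.normal(200, 10, 5000)]
        )
        h, _ = np.histogram(np.clip(samples, 0, 255), bins=256, range=(0, 256))
        t = otsu_threshold(h)
        assert 60 < t < 200
        assert t == otsu_oracle(h)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=8, max_size=64)
        .filter(lambda h: sum(1 for v in h if v > 0) >= 2)
    )
    def test_property_equals_exhaustive_argmax(self, hist):
        h = np.asarray(hist)
        assert otsu_threshold(h) == otsu_oracle(h)

    def test_degenerate_single_bin(self):
        h = np.zeros(256)
        h[17] = 100
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(h)

    def test_empty_histogram(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.zeros(256))


class TestSegmentTissue:
    def test_pure_white_has_no_tissue(self):
        img = np.full((256, 256, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning):
            mask = segment_tissue(img, downsample=4)
        assert mask.tissue_fraction == 0.0

    def test_half_white_half_pink(self):
        img = np.full((256, 256, 3), 255, dtype=np.uint8)
        img[:, :128] = (230, 80, 160)  # saturated pink
        mask = segment_tissue(img, downsample=2)
        expected = np.zeros(mask.mask.shape, dtype=bool)
        expected[:, : mask.mask.shape[1] // 2] = True
        mismatch = np.mean(mask.mask != expected)
        assert mismatch < 0.02

    def test_synthetic_slide_iou(self, small_cfg, small_slide):
        img, truth = small_slide
        mask = segment_tissue(img, downsample=4)
        gt = truth.tissue_mask()
        gt_low = gt[:: mask.downsample, :: mask.downsample][
            : mask.mask.shape[0], : mask.mask.shape[1]
        ]
        inter = np.sum(mask.mask & gt_low)
        union = np.sum(mask.mask | gt_low)
        assert inter / union >= 0.95

    def test_invariant_to_white_padding(self, small_slide):
        img, _ = small_slide
        mask = segment_tissue(img, downsample=4)
        pad = 64
        padded = np.full(
            (img.shape[0] + 2 * pad, img.shape[1] + 2 * pad, 3), 255, dtype=np.uint8
        )
        padded[pad:-pad, pad:-pad] = img
        mask_p = segment_tissue(padded, downsample=4)
        d = mask.downsample
        inner = mask_p.mask[pad // d : pad // d + mask.mask.shape[0],
                            pad // d : pad // d + mask.mask.shape[1]]
        agreement = np.mean(inner == mask.mask)
        assert agreement > 0.98


class TestTilePatches:
    def _all_tissue_mask(self, h, w, d=4):
        return TissueMask(np.ones((h // d, w // d), dtype=bool), d, 10.0)

    def test_all_tissue_grid_count(self):
        mask = self._all_tissue_mask(4096, 4096)
        refs = tile_patches((4096, 4096), mask, patch_size=1024)
        assert len(refs) == 16

    @pytest.mark.parametrize(
        "shape,size,expected",
        [((1023, 4096), 1024, 0), ((2048, 3072), 1024, 6), ((100, 100), 101, 0)],
    )
    def test_floor_division_counts(self, shape, size, expected):
        mask = TissueMask(np.ones((max(shape[0] // 4, 1), max(shape[1] // 4, 1)), bool), 4, 0.0)
        assert len(tile_patches(shape, mask, patch_size=size)) == expected

    def test_left_half_mask(self):
        m = np.zeros((512, 512), dtype=bool)
        m[:, :256] = True
        mask = TissueMask(m, 4, 0.0)
        refs = tile_patches((2048, 2048), mask, patch_size=1024, min_tissue_fraction=0.5)
        assert len(refs) == 2
        assert all(r.x == 0 for r in refs)

    def test_patches_disjoint_and_inside(self, small_cfg, small_slide):
        img, _ = small_slide
        mask = segment_tissue(img, downsample=4)
        refs = tile_patches(img, mask, patch_size=small_cfg.patch_size)
        seen = set()
        H, W = img.shape[:2]
        for r in refs:
            key = (r.x, r.y)
            assert key not in seen
            seen.add(key)
            assert r.x % r.size == 0 and r.y % r.size == 0
            assert r.x + r.size <= W and r.y + r.size <= H
            assert r.tissue_fraction >= 0.5

    def test_row_major_order(self):
        mask = self._all_tissue_mask(2048, 2048)
        refs = tile_patches((2048, 2048), mask, patch_size=1024)
        coords = [(r.y, r.x) for r in refs]
        assert coords == sorted(coords)

    def test_manifest_roundtrip(self, tmp_path):
        refs = [
            PatchRef("s1", 0, 1024, 1024, 0.8, label="GBM", patient_id="p1"),
            PatchRef("s1", 1024, 1024, 1024, 1.0, label="GBM", patient_id="p1"),
        ]
        path = tmp_path / "manifest.csv"
        write_patch_manifest(refs, path)
        back = read_patch_manifest(path)
        assert [(r.x, r.y, r.label) for r in back] == [(r.x, r.y, r.label) for r in refs]
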