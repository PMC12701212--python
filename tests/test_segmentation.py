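"""Thresholding, morphology (with a brute-force set-theoretic oracle),
periphery removal, ROI extraction and ground-truth labeling."""

import numpy as np
import pytest

from mammodelta.data_model_io import AnnotationMask
from mammodelta.segmentation import (
    SegmentationConfig,
    assign_gt_labels,
    binarize,
    extract_rois,
    morph_clean,
    remove_periphery,
    segment_image,
    select_threshold,
)
from mammodelta.subtraction import SubtractionImage


def _disk_offsets(radius):
    rr, cc = np.meshgrid(
        np.arange(-radius, radius + 1), np.arange(-radius, radius + 1), indexing="ij"
    )
    keep = rr**2 + cc**2 <= radius**2
    return list(zip(rr[keep].tolist(), cc[keep].tolist()))


def brute_erosion(grid, radius):
    """Set-theoretic erosion: p kept iff the whole disk around p is foreground
    (background outside the frame)."""
    rows, cols = grid.shape
    offs = _disk_offsets(radius)
    out = np.zeros_like(grid, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            if not grid[r, c]:
                continue
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if rr < 0 or rr >= rows or cc < 0 or cc >= cols or not grid[rr, cc]:
                    ok = False
                    break
            out[r, c] = ok
    return out


def brute_closing(grid, radius):
    """Set-theoretic closing on the infinite plane, restricted to the frame."""
    rows, cols = grid.shape
    pad = radius
    big = np.zeros((rows + 2 * pad, cols + 2 * pad), dtype=bool)
    big[pad:-pad, pad:-pad] = grid
    offs = _disk_offsets(radius)
    dil = np.zeros_like(big)
    for r, c in zip(*np.nonzero(big)):
        for dr, dc in offs:
            dil[r + dr, c + dc] = True
    ero = np.zeros_like(big)
    for r in range(big.shape[0]):
        for c in range(big.shape[1]):
            if not dil[r, c]:
                continue
            ok = True
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if (
                    rr < 0 or rr >= big.shape[0] or cc < 0 or cc >= big.shape[1]
                    or not dil[rr, cc]
                ):
                    ok = False
                    break
            ero[r, c] = ok
    return ero[pad:-pad, pad:-pad]


class TestBinarize:
    def test_strictly_above(self):
        img = np.array([[0.4, 0.6], [0.5, 0.0]])
        out = binarize(img, 0.5)
        np.testing.assert_array_equal(out, [[False, True], [False, False]])

    def test_all_zero(self):
        assert not binarize(np.zeros((5, 5)), 0.3).any()

    def test_monotone_in_threshold(self, rng):
        img = rng.random((32, 32))
        lo = binarize(img, 0.3)
        hi = binarize(img, 0.6)
        assert not (hi & ~lo).any()

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((3, 3)), 1.5)


class TestMorphology:
    def test_isolated_pixel_removed(self):
        g = np.zeros((20, 20), dtype=bool)
        g[10, 10] = True
        assert not morph_clean(g).any()

    def test_two_disks_merge_across_gap(self):
        g = np.zeros((40, 80), dtype=bool)
        rr, cc = np.meshgrid(np.arange(40), np.arange(80), indexing="ij")
        g |= np.hypot(rr - 20, cc - 20) <= 8
        g |= np.hypot(rr - 20, cc - 48) <= 8  # 12-px gap between disk edges
        out = morph_clean(g, erosion_radius=0, closing_radius=10)
        from scipy import ndimage

        _, n = ndimage.label(out, structure=np.ones((3, 3)))
        assert n == 1

    def test_square_erosion_bound(self):
        g = np.zeros((70, 70), dtype=bool)
        g[10:60, 10:60] = True  # solid 50x50 square
        out = morph_clean(g, erosion_radius=2, closing_radius=10)
        from scipy import ndimage

        _, n = ndimage.label(out, structure=np.ones((3, 3)))
        assert n == 1
        # erosion shrinks each side by <= 2 px; closing of a convex set restores nothing
        assert 46 * 46 <= out.sum() <= 50 * 50

    @pytest.mark.parametrize("seed", range(6))
    def test_against_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.random((64, 64)) > 0.82
        expected = brute_closing(brute_erosion(g, 2), 10)
        np.testing.assert_array_equal(morph_clean(g, 2, 10), expected)


class TestPeriphery:
    @staticmethod
    def _breast(shape=(64, 64)):
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        m = ((rr - 32) / 28.0) ** 2 + (cc / 55.0) ** 2 <= 1
        return AnnotationMask(m.astype(np.uint8))

    def test_border_component_removed(self):
        breast = self._breast()
        g = np.zeros((64, 64), dtype=bool)
        g[30:34, 50:55] = True  # near the breast boundary
        out = remove_periphery(g, breast, band=15)
        assert not out.any()

    def test_interior_component_kept(self):
        breast = self._breast()
        g = np.zeros((64, 64), dtype=bool)
        g[30:34, 10:14] = True
        out = remove_periphery(g, breast, band=10)
        assert out.sum() == 16

    def test_outside_breast_removed(self):
        breast = self._breast()
        g = np.zeros((64, 64), dtype=bool)
        g[2:6, 60:64] = True
        assert not remove_periphery(g, breast, band=5).any()

    def test_skin_line_ribbon_removed(self):
        breast = self._breast()
        edge = breast.pixels & ~np.pad(breast.pixels, 1)[2:, 1:-1]
        g = edge.copy()
        assert g.any()
        assert not remove_periphery(g, breast, band=10).any()

    def test_empty_breast_rejected(self):
        with pytest.raises(ValueError):
            remove_periphery(np.zeros((8, 8), bool), AnnotationMask(np.zeros((8, 8))), 2)


class TestExtract:
    def test_three_blobs(self):
        g = np.zeros((50, 50), dtype=bool)
        g[5:10, 5:10] = g[20:26, 20:26] = g[40:46, 5:11] = True
        rois = extract_rois(g, min_area=9)
        assert len(rois) == 3
        assert [r.roi_id for r in rois] == [0, 1, 2]
        # raster order by bbox
        assert rois[0].bbox[0] <= rois[1].bbox[0] <= rois[2].bbox[0]

    def test_empty_grid(self):
        assert extract_rois(np.zeros((10, 10), bool)) == []

    def test_min_area_filter(self):
        g = np.zeros((20, 20), dtype=bool)
        g[2:4, 2:4] = True  # 4 px
        g[10:14, 10:14] = True  # 16 px
        rois = extract_rois(g, min_area=9)
        assert len(rois) == 1 and rois[0].area == 16

    def test_centroid_inside_bbox(self, rng):
        g = rng.random((64, 64)) > 0.9
        for roi in extract_rois(g, min_area=1):
            r0, c0, r1, c1 = roi.bbox
            assert r0 <= roi.centroid[0] < r1
            assert c0 <= roi.centroid[1] < c1


class TestLabels:
    @staticmethod
    def _roi_grid():
        g = np.zeros((40, 40), dtype=bool)
        g[5:15, 5:15] = True
        return extract_rois(g)[0]

    def test_full_overlap(self):
        roi = self._roi_grid()
        mask = AnnotationMask(np.ones((40, 40), dtype=np.uint8))
        assert assign_gt_labels([roi], mask)[0].gt_label == "future_malignant"

    def test_disjoint(self):
        roi = self._roi_grid()
        m = np.zeros((40, 40), dtype=np.uint8)
        m[30:35, 30:35] = 1
        assert assign_gt_labels([roi], AnnotationMask(m))[0].gt_label == "normal"

    def test_overlap_rule_boundary(self):
        roi = self._roi_grid()  # 100 px
        m = np.zeros((40, 40), dtype=np.uint8)
        m[5:15, 5:8] = 1  # 30 px overlap = 30%
        mask = AnnotationMask(m)
        assert assign_gt_labels([roi], mask, overlap_fraction=0.25)[0].gt_label == (
            "future_malignant"
        )
        assert assign_gt_labels([roi], mask, overlap_fraction=0.5)[0].gt_label == "normal"

    def test_no_mask_all_normal(self):
        roi = self._roi_grid()
        assert assign_gt_labels([roi], None)[0].gt_label == "normal"


class TestSelectThreshold:
    @staticmethod
    def _image_with_truth():
        """Truth blob at 0.6; background speckle at 0.25."""
        px = np.zeros((64, 64))
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        breast = ((rr - 32) / 28.0) ** 2 + (cc / 55.0) ** 2 <= 1
        rng = np.random.default_rng(0)
        px[breast] = 0.05 + 0.02 * rng.random(breast.sum())
        blob = np.hypot(rr - 32, cc - 20) <= 6
        px[blob] = 0.6
        gt = AnnotationMask(blob.astype(np.uint8))
        return (
            SubtractionImage(px, "p", "CC"),
            gt,
            AnnotationMask(breast.astype(np.uint8)),
        )

    def test_separable_case(self):
        img, gt, breast = self._image_with_truth()
        cfg = SegmentationConfig(periphery_band=5)
        thr = select_threshold([img], [gt], [breast], cfg)
        assert thr <= 0.6
        rois = segment_image(img, breast, thr, cfg)
        rois = assign_gt_labels(rois, gt)
        assert any(r.gt_label == "future_malignant" for r in rois)

    def test_tie_resolves_to_lowest(self):
        # every candidate recovers the blob -> lowest candidate returned
        img, gt, breast = self._image_with_truth()
        cfg = SegmentationConfig(periphery_band=5)
        thr = select_threshold([img], [gt], [breast], cfg)
        import numpy as np

        pooled = img.pixels[img.pixels > 0]
        lowest = np.clip(np.percentile(pooled, cfg.candidate_percentiles[0]), 1e-6, 1 - 1e-6)
        assert thr == pytest.approx(float(lowest))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            select_threshold([], [], [])
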