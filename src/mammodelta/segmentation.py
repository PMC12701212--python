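"""Candidate-ROI segmentation of the enhanced subtraction image.

Three steps: (1) thresholding removes low-intensity normal areas, (2)
morphology — erosion with a 2-px disk deletes isolated registration/threshold
debris, then closing with a 10-px disk merges the constituents of one mass —
and (3) periphery removal deletes high-intensity skin-line regions along the
breast border, where masses cannot form. The surviving 8-connected
components are the ROIs; each is then labeled against the propagated
ground-truth mask of the future mass (when one exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .data_model_io import AnnotationMask
from .subtraction import SubtractionImage

_CONN8 = np.ones((3, 3), dtype=int)


class GtLabel:
    NORMAL = "normal"
    FUTURE_MALIGNANT = "future_malignant"
    UNASSIGNED = "unassigned"


@dataclass
class ROI:
    """One 8-connected component of the cleaned binary subtraction image."""

    roi_id: int
    mask: np.ndarray  # bool, full-image grid
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float]
    gt_label: str = GtLabel.UNASSIGNED

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def patch_slices(self) -> tuple[slice, slice]:
        r0, c0, r1, c1 = self.bbox
        return slice(r0, r1), slice(c0, c1)


@dataclass
class SegmentationConfig:
    threshold: float | str = "auto"
    erosion_radius: int = 2
    closing_radius: int = 10
    periphery_band: int = 15
    min_area: int = 9
    overlap_fraction: float = 0.25
    # candidate thresholds = these percentiles of pooled nonzero intensities
    candidate_percentiles: tuple[float, ...] = (80.0, 85.0, 90.0, 92.5, 95.0, 97.5, 99.0)

    def __post_init__(self) -> None:
        if self.erosion_radius < 0 or self.closing_radius < 0:
            raise ValueError("morphology radii must be >= 0")


def binarize(img: SubtractionImage | np.ndarray, threshold: float) -> np.ndarray:
    """Foreground = pixels strictly above the threshold (in (0, 1))."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    px = img.pixels if isinstance(img, SubtractionImage) else np.asarray(img)
    return px > threshold


def morph_clean(
    binary: np.ndarray, erosion_radius: int = 2, closing_radius: int = 10
) -> np.ndarray:
    """Erosion (disk r=2) to drop isolated debris, then closing (disk r=10)
    to merge the fragments of a single mass.

    Semantics are those of set morphology on the infinite plane with
    background outside the frame: the closing is computed on a frame padded
    by its radius so that dilation never wraps or clips at the border.
    """
    out = np.asarray(binary, dtype=bool)
    if erosion_radius > 0:
        out = ndimage.binary_erosion(out, structure=disk(erosion_radius))
    r = closing_radius
    if r > 0:
        padded = np.pad(out, r, constant_values=False)
        padded = ndimage.binary_dilation(padded, structure=disk(r))
        padded = ndimage.binary_erosion(padded, structure=disk(r))
        out = padded[r:-r, r:-r]
    return out


def remove_periphery(
    binary: np.ndarray, breast_mask: AnnotationMask, band: int = 15
) -> np.ndarray:
    """Delete components outside the breast or touching its border band.

    The border band is the set of breast pixels within ``band`` px of the
    breast boundary; any component intersecting it (skin line, edge
    artifacts) is removed whole.
    """
    breast = breast_mask.pixels
    if not breast.any():
        raise ValueError("empty breast mask")
    interior = ndimage.binary_erosion(breast, iterations=band) if band > 0 else breast
    border_band = breast & ~interior
    labels, n = ndimage.label(np.asarray(binary, bool), structure=_CONN8)
    if n == 0:
        return np.zeros_like(breast, dtype=bool)
    keep = np.zeros(n + 1, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        if not (comp & ~breast).any() and not (comp & border_band).any():
            keep[lab] = True
    return keep[labels]


def extract_rois(binary: np.ndarray, min_area: int = 9) -> list[ROI]:
    """One ROI per 8-connected component with area >= min_area, ordered by
    the raster position of the bounding box."""
    labels, n = ndimage.label(np.asarray(binary, bool), structure=_CONN8)
    objs = ndimage.find_objects(labels)
    rois: list[ROI] = []
    for lab, slc in enumerate(objs, start=1):
        if slc is None:
            continue
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        r0, r1 = slc[0].start, slc[0].stop
        c0, c1 = slc[1].start, slc[1].stop
        rr, cc = np.nonzero(comp)
        rois.append(
            ROI(
                roi_id=-1,
                mask=comp,
                bbox=(r0, c0, r1, c1),
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
    rois.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    for i, roi in enumerate(rois):
        roi.roi_id = i
    return rois


def assign_gt_labels(
    rois: list[ROI],
    propagated_mask: AnnotationMask | None,
    overlap_fraction: float = 0.25,
) -> list[ROI]:
    """Label each ROI future_malignant iff |roi ∩ mask| / |roi| >= the
    overlap fraction; all ROIs are normal when no mask exists (normal case)."""
    for roi in rois:
        if propagated_mask is None:
            roi.gt_label = GtLabel.NORMAL
            continue
        inter = int((roi.mask & propagated_mask.pixels).sum())
        frac = inter / max(roi.area, 1)
        roi.gt_label = (
            GtLabel.FUTURE_MALIGNANT if frac >= overlap_fraction else GtLabel.NORMAL
        )
    return rois


def segment_image(
    img: SubtractionImage,
    breast_mask: AnnotationMask,
    threshold: float,
    cfg: SegmentationConfig | None = None,
) -> list[ROI]:
    """Full 3-step segmentation at a given threshold."""
    cfg = cfg or SegmentationConfig()
    binary = binarize(img, threshold)
    binary = morph_clean(binary, cfg.erosion_radius, cfg.closing_radius)
    binary = remove_periphery(binary, breast_mask, cfg.periphery_band)
    return extract_rois(binary, cfg.min_area)


def _global_classification_rate(
    rois: list[ROI], gt_mask: AnnotationMask | None
) -> tuple[int, int]:
    """(n_correct, n_total) for threshold scoring: an image's ROI set is
    scored by ground-truth recovery (every GT component is hit by some ROI)
    and each ROI by whether its label is consistent with GT overlap."""
    correct = 0
    total = 0
    if gt_mask is not None and not gt_mask.is_empty():
        comp_labels = gt_mask.labeled_components()
        n_comp = comp_labels.max()
        for comp in range(1, n_comp + 1):
            comp_mask = comp_labels == comp
            total += 1
            if any((roi.mask & comp_mask).any() for roi in rois):
                correct += 1
    return correct, total


def select_threshold(
    images: list[SubtractionImage],
    gt_masks: list[AnnotationMask | None],
    breast_masks: list[AnnotationMask],
    cfg: SegmentationConfig | None = None,
) -> float:
    """Pick the candidate threshold maximizing the training-set global
    classification rate (ground-truth blobs recovered as ROIs, normal area
    rejected); ties resolve to the lower threshold.

    Candidates are percentiles of the pooled nonzero subtraction histogram.
    """
    cfg = cfg or SegmentationConfig()
    if not images:
        raise ValueError("empty training set")
    pooled = np.concatenate([im.pixels[im.pixels > 0].ravel() for im in images])
    if pooled.size == 0:
        raise ValueError("all-zero training images")
    candidates = sorted(
        float(np.clip(np.percentile(pooled, p), 1e-6, 1 - 1e-6))
        for p in cfg.candidate_percentiles
    )
    best_thr, best_score = None, -np.inf
    for thr in candidates:  # ascending, so ties resolve to the lower threshold
        hit, total = 0, 0
        for im, gt, breast in zip(images, gt_masks, breast_masks):
            rois = segment_image(im, breast, thr, cfg)
            h, t = _global_classification_rate(rois, gt)
            hit += h
            total += t
        recovery = hit / total if total else 1.0
        if recovery > best_score + 1e-12:
            best_score, best_thr = recovery, thr
    assert best_thr is not None
    return best_thr
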