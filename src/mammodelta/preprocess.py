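"""Image enhancement and breast-region isolation.

The same chain runs on every round before registration or subtraction:
min–max normalization, CLAHE, gamma correction, and border removal.
All operations are deterministic, shape-preserving, and — for the point
maps (normalization, gamma) — strictly monotone in intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .data_model_io import AnnotationMask, Mammogram, MaskSource


@dataclass
class PreprocessConfig:
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    gamma: float = 0.8
    border_margin: int = 5

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")


def normalize_intensity(img: Mammogram) -> Mammogram:
    """Min–max rescale to [0, 1]; a constant image maps to all zeros."""
    px = img.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return img.with_pixels(np.zeros_like(px))
    return img.with_pixels((px - lo) / (hi - lo))


def apply_clahe(
    img: Mammogram,
    clip: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
) -> Mammogram:
    """Contrast limited adaptive histogram equalization on a [0, 1] image."""
    px = img.pixels
    if tiles[0] > px.shape[0] or tiles[1] > px.shape[1]:
        raise ValueError(f"tile grid {tiles} larger than image {px.shape}")
    if px.max() == px.min():
        # no histogram to equalize
        return img.with_pixels(px.copy())
    kernel = (
        max(1, px.shape[0] // tiles[0]),
        max(1, px.shape[1] // tiles[1]),
    )
    out = exposure.equalize_adapthist(
        np.clip(px, 0.0, 1.0), kernel_size=kernel, clip_limit=clip
    )
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def gamma_correct(img: Mammogram, gamma: float) -> Mammogram:
    """Elementwise power-law mapping ``out = in ** gamma`` on [0, 1] data."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return img.with_pixels(np.power(np.clip(img.pixels, 0.0, None), gamma))


def remove_border(img: Mammogram, margin: int) -> Mammogram:
    """Zero a frame of ``margin`` pixels; suppresses scanner-edge artifacts."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rows, cols = img.pixels.shape
    if margin >= min(rows, cols) / 2:
        raise ValueError(f"margin {margin} >= half the smaller dimension")
    if margin == 0:
        return img.with_pixels(img.pixels.copy())
    out = np.zeros_like(img.pixels)
    out[margin:-margin, margin:-margin] = img.pixels[margin:-margin, margin:-margin]
    return img.with_pixels(out)


def segment_breast(img: Mammogram, threshold: float | None = None) -> AnnotationMask:
    """Binarize the breast and keep the single largest connected component.

    ``threshold`` defaults to a small fraction of the intensity range above
    the background level, which cleanly separates the tissue support from
    the (near-zero) background of a preprocessed mammogram; off-breast
    labels and markers are dropped by the largest-component rule. Small
    interior holes are filled.
    """
    px = img.pixels
    if threshold is None:
        threshold = float(px.min()) + 0.05 * (float(px.max()) - float(px.min()))
    fg = px > threshold
    if not fg.any():
        raise ValueError("empty foreground: cannot segment breast region")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(labels == largest)
    return AnnotationMask(pixels=mask.astype(np.uint8), source=MaskSource.SYNTHETIC)


def preprocess_image(img: Mammogram, cfg: PreprocessConfig | None = None) -> Mammogram:
    """Full enhancement chain: normalize -> CLAHE -> gamma -> border removal."""
    cfg = cfg or PreprocessConfig()
    out = normalize_intensity(img)
    out = apply_clahe(out, clip=cfg.clahe_clip, tiles=cfg.clahe_tiles)
    out = gamma_correct(out, cfg.gamma)
    out = remove_border(out, cfg.border_margin)
    return out
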