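"""Temporal subtraction and high-frequency enhancement.

Subtracting the registered prior mammogram from the current one suppresses
static anatomy and highlights interval change: a mass precursor that has
appeared (or brightened) since the prior round survives as a bright blob.
Negative differences are clipped by default — new masses are bright
structures — with a switch for signed output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_model_io import AnnotationMask, Mammogram


@dataclass
class SubtractionImage:
    pixels: np.ndarray
    patient_id: str
    view: str
    enhancement_applied: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("subtraction image must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("subtraction image must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def temporal_subtract(
    current: Mammogram,
    prior_registered: Mammogram,
    clip_negative: bool = True,
) -> SubtractionImage:
    """``current - prior_registered``; negatives clipped to 0 by default."""
    if current.shape != prior_registered.shape:
        raise ValueError(
            f"shape mismatch: {current.shape} vs {prior_registered.shape}"
        )
    diff = current.pixels - prior_registered.pixels
    if clip_negative:
        diff = np.clip(diff, 0.0, None)
    return SubtractionImage(
        pixels=diff,
        patient_id=current.patient_id,
        view=current.view.value,
    )


def unsharp_enhance(
    img: SubtractionImage, radius: float = 5.0, amount: float = 1.0
) -> SubtractionImage:
    """Unsharp masking: ``out = img + amount * (img - blur(img, radius))``.

    Boosts the high spatial frequencies carrying mass edges; output is
    clipped at 0 to remain a non-negative change map.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    blurred = ndimage.gaussian_filter(img.pixels, radius)
    out = np.clip(img.pixels + amount * (img.pixels - blurred), 0.0, None)
    return SubtractionImage(
        pixels=out,
        patient_id=img.patient_id,
        view=img.view,
        enhancement_applied=True,
    )


def contrast_ratio(
    pixels: np.ndarray,
    mask: AnnotationMask,
    annulus_width: int = 10,
    eps: float = 1e-6,
) -> float:
    """Mean intensity inside the mask over mean intensity in a surrounding
    annulus (mask dilated by ``annulus_width`` minus the mask)."""
    m = mask.pixels
    if not m.any():
        raise ValueError("empty mask")
    dilated = ndimage.binary_dilation(m, iterations=annulus_width)
    annulus = dilated & ~m
    if not annulus.any():
        raise ValueError("empty background annulus")
    inside = float(np.mean(pixels[m]))
    outside = max(float(np.mean(pixels[annulus])), eps)
    return inside / outside
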