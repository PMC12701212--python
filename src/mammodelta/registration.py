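"""Deformable registration of sequential mammograms.

Thirion's demons algorithm is used twice in the workflow: once to map the
future-round mass annotation back onto the current image (ground-truth
localization), and once to align the prior image with the current one before
temporal subtraction. The displacement field is estimated with SimpleITK's
demons filter inside a hand-rolled multi-resolution pyramid; the field is
regularized by Gaussian smoothing each iteration and the whole procedure is
deterministic (no random initialization).

Displacement convention: for every pixel ``x`` of the *fixed* (current)
grid, ``displacements[x]`` is the (row, col) offset such that
``warped_moving(x) = moving(x + d(x))`` (backward warping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .data_model_io import AnnotationMask, Mammogram, MaskSource


@dataclass
class DeformationField:
    """Dense per-pixel 2-D displacement (in pixels) on the fixed grid."""

    displacements: np.ndarray  # shape (rows, cols, 2), (d_row, d_col)
    fixed_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.shape != (*self.fixed_shape, 2):
            raise ValueError(
                f"field shape {self.displacements.shape} does not match "
                f"fixed grid {self.fixed_shape}"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement components must be finite")

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "DeformationField":
        return cls(np.zeros((*shape, 2)), tuple(shape))

    @classmethod
    def constant_shift(cls, shape: tuple[int, int], d_row: float, d_col: float) -> "DeformationField":
        d = np.empty((*shape, 2))
        d[..., 0] = d_row
        d[..., 1] = d_col
        return cls(d, tuple(shape))

    def mean_magnitude(self) -> float:
        return float(np.mean(np.hypot(self.displacements[..., 0], self.displacements[..., 1])))


@dataclass
class DemonsConfig:
    levels: int = 3
    iterations_per_level: list[int] = field(default_factory=lambda: [50, 30, 10])
    smoothing_sigma: float = 2.0
    convergence_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be > 0")
        if len(self.iterations_per_level) != self.levels:
            raise ValueError("iterations_per_level must list one entry per level")


def pad_to_common_shape(a: Mammogram, b: Mammogram) -> tuple[Mammogram, Mammogram]:
    """Zero-pad both images (bottom/right) to their elementwise max shape."""
    rows = max(a.shape[0], b.shape[0])
    cols = max(a.shape[1], b.shape[1])

    def _pad(img: Mammogram) -> Mammogram:
        if img.shape == (rows, cols):
            return img
        out = np.zeros((rows, cols))
        out[: img.shape[0], : img.shape[1]] = img.pixels
        return img.with_pixels(out)

    return _pad(a), _pad(b)


def _to_sitk(arr: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(arr.astype(np.float32))


def demons_register(
    fixed: Mammogram,
    moving: Mammogram,
    cfg: DemonsConfig | None = None,
) -> DeformationField:
    """Estimate the dense field warping ``moving`` onto ``fixed``.

    Classic (Thirion) demons with Gaussian field regularization, run
    coarse-to-fine over a ``cfg.levels``-deep pyramid; the coarse solution
    is upsampled and used to initialize the next level.
    """
    cfg = cfg or DemonsConfig()
    if fixed.shape != moving.shape:
        raise ValueError(
            f"shape mismatch {fixed.shape} vs {moving.shape}; pad to a common "
            "shape before registration"
        )
    f_img = _to_sitk(fixed.pixels)
    m_img = _to_sitk(moving.pixels)

    shrinks = [2 ** (cfg.levels - 1 - lv) for lv in range(cfg.levels)]
    disp: sitk.Image | None = None
    for shrink, n_iter in zip(shrinks, cfg.iterations_per_level):
        if shrink > 1:
            f_lv = sitk.Shrink(f_img, [shrink, shrink])
            m_lv = sitk.Shrink(m_img, [shrink, shrink])
        else:
            f_lv, m_lv = f_img, m_img
        demons = sitk.DemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(n_iter))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(cfg.smoothing_sigma)
        if disp is not None:
            disp = sitk.Resample(
                disp, f_lv, sitk.Transform(), sitk.sitkLinear, 0.0,
                sitk.sitkVectorFloat64,
            )
            disp = demons.Execute(f_lv, m_lv, disp)
        else:
            disp = demons.Execute(f_lv, m_lv)
    assert disp is not None
    # field components come back as (x, y) = (col, row) in unit-spacing physical coords
    arr = sitk.GetArrayFromImage(disp)  # (rows, cols, 2) -> [..., 0]=dx(col), [..., 1]=dy(row)
    out = np.empty((*fixed.shape, 2))
    out[..., 0] = arr[..., 1]
    out[..., 1] = arr[..., 0]
    return DeformationField(out, fixed.shape)


def warp_image(img: Mammogram, fld: DeformationField, order: int = 1) -> Mammogram:
    """Backward-warp ``img`` by the field (bilinear; out of bounds -> 0)."""
    if fld.fixed_shape != img.shape:
        raise ValueError(f"field grid {fld.fixed_shape} != image shape {img.shape}")
    rows, cols = img.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack(
        [rr + fld.displacements[..., 0], cc + fld.displacements[..., 1]]
    )
    out = ndimage.map_coordinates(
        img.pixels, coords, order=order, mode="constant", cval=0.0
    )
    return img.with_pixels(np.clip(out, 0.0, None))


def warp_array(arr: np.ndarray, fld: DeformationField, order: int = 1) -> np.ndarray:
    """Backward-warp a raw float array by the field."""
    rows, cols = arr.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack(
        [rr + fld.displacements[..., 0], cc + fld.displacements[..., 1]]
    )
    return ndimage.map_coordinates(arr, coords, order=order, mode="constant", cval=0.0)


def propagate_future_mask(
    future_mask: AnnotationMask, fld: DeformationField
) -> AnnotationMask:
    """Map a future-round mass annotation onto the current grid.

    The field must come from registering *future* (moving) to *current*
    (fixed). The binary mask is warped as a float image and re-thresholded
    at 0.5, which approximately preserves area under smooth fields.
    """
    if fld.fixed_shape != future_mask.shape:
        raise ValueError("field grid does not match mask shape")
    warped = warp_array(future_mask.pixels.astype(np.float64), fld, order=1)
    out = warped >= 0.5
    if not out.any():
        raise ValueError(
            "propagated mask is empty (mass warped out of frame); flag for review"
        )
    return AnnotationMask(pixels=out.astype(np.uint8), source=MaskSource.PROPAGATED)


def ssd(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of squared differences, the demons matching criterion."""
    return float(np.sum((np.asarray(a, float) - np.asarray(b, float)) ** 2))
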