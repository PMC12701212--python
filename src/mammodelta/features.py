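"""Per-ROI feature extraction: a fixed 98-name registry.

Groups (registry order):

* 15 shape features of the ROI support (region properties plus
  ``Circularity = 4*pi*A/P^2``, ``Compactness = P^2/(4*pi*A)`` and
  ``Shape Ratio = major/minor axis length``);
* 9 intensity / first-order statistics of the enhanced subtraction image
  over the ROI pixels (``Smoothness = 1 - 1/(1+Variance)``; Entropy in bits
  over a 32-bin histogram);
* 72 GLCM texture values: for each offset D in {5, 15, 25} px and each base
  statistic in {Contrast, Correlation, Energy, Homogeneity}, the four
  directional values (0/45/90/135 degrees) plus their mean and STD — 24
  values per offset. Co-occurrence matrices are symmetric and normalized,
  computed on the ROI's bounding-box patch quantized to 32 gray levels over
  the patch's own range (so texture is invariant to additive intensity
  shifts). A constant patch has Contrast 0, Energy 1, Homogeneity 1 and —
  by the degenerate-variance rule — Correlation 0.
* 2 epidemiological values: patient age (years) and BI-RADS density a–d
  encoded 1–4.

The registry reconstructs a 98-value vector containing every feature name
used by the ranking stage; the exact complement beyond the named ones is a
documented reconstruction, not a canonical list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

from .data_model_io import DENSITY_CODES
from .segmentation import ROI

REGISTRY_VERSION = "1.0"

SHAPE_FEATURES = [
    "Area",
    "Convex Area",
    "Filled Area",
    "Perimeter",
    "Major Axis Length",
    "Minor Axis Length",
    "Equivalent Diameter",
    "Eccentricity",
    "Solidity",
    "Extent",
    "Orientation",
    "Euler Number",
    "Circularity",
    "Compactness",
    "Shape Ratio",
]

INTENSITY_FEATURES = [
    "Mean Intensity",
    "Max Intensity",
    "Min Intensity",
    "STD",
    "Variance",
    "Smoothness",
    "Skewness",
    "Kurtosis",
    "Entropy",
]

GLCM_BASES = ["Contrast", "Correlation", "Energy", "Homogeneity"]
GLCM_ANGLES_DEG = [0, 45, 90, 135]
GLCM_VALUE_TAGS = [str(a) for a in GLCM_ANGLES_DEG] + ["Mean", "STD"]

EPI_FEATURES = ["Patient Age", "Breast Density"]


@dataclass
class GlcmSpec:
    offsets: tuple[int, int, int] = (5, 15, 25)
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    gray_levels: int = 32

    def __post_init__(self) -> None:
        if list(self.offsets) != sorted(self.offsets) or min(self.offsets) <= 0:
            raise ValueError("offsets must be positive and increasing")
        if len(self.angles_deg) != 4:
            raise ValueError("exactly 4 angles expected")

    def offset_tag(self, i: int) -> str:
        return f"D{i + 1}"


def glcm_feature_names(spec: GlcmSpec | None = None) -> list[str]:
    spec = spec or GlcmSpec()
    names = []
    for i in range(len(spec.offsets)):
        tag = spec.offset_tag(i)
        for base in GLCM_BASES:
            for val in GLCM_VALUE_TAGS:
                names.append(f"{base} {val} {tag}")
    return names


def feature_registry(spec: GlcmSpec | None = None) -> list[str]:
    """The fixed, ordered list of all 98 feature names."""
    return SHAPE_FEATURES + INTENSITY_FEATURES + glcm_feature_names(spec) + EPI_FEATURES


@dataclass
class FeatureVector:
    values: dict[str, float]
    registry_version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        if len(self.values) != 98:
            raise ValueError(f"expected 98 features, got {len(self.values)}")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")

    def as_array(self, registry: list[str]) -> np.ndarray:
        return np.array([self.values[name] for name in registry], dtype=float)


# ---------------------------------------------------------------------------


def shape_features(roi: ROI) -> dict[str, float]:
    if roi.area == 0:
        raise ValueError("empty ROI mask")
    rs, cs = roi.patch_slices()
    patch = roi.mask[rs, cs].astype(np.uint8)
    props = regionprops(patch)[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    p2 = max(perimeter, 1e-12) ** 2
    out = {
        "Area": area,
        "Convex Area": float(props.area_convex),
        "Filled Area": float(props.area_filled),
        "Perimeter": perimeter,
        "Major Axis Length": major,
        "Minor Axis Length": minor,
        "Equivalent Diameter": float(props.equivalent_diameter_area),
        "Eccentricity": float(props.eccentricity),
        "Solidity": float(props.solidity),
        "Extent": float(props.extent),
        "Orientation": float(props.orientation),
        "Euler Number": float(props.euler_number),
        "Circularity": 4.0 * math.pi * area / p2,
        "Compactness": p2 / (4.0 * math.pi * area),
        "Shape Ratio": major / max(minor, 1e-12),
    }
    return out


def intensity_fos_features(roi: ROI, pixels: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    vals = pixels[roi.mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = float(vals.mean())
    var = float(vals.var())
    std = math.sqrt(var)
    if std > 0:
        z = (vals - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew = kurt = 0.0
    # Shannon entropy (bits) of the intensity histogram over the ROI
    if np.ptp(vals) > 0:
        hist, _ = np.histogram(vals, bins=n_bins)
    else:
        hist = np.array([vals.size])
    p = hist[hist > 0] / vals.size
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "Mean Intensity": mean,
        "Max Intensity": float(vals.max()),
        "Min Intensity": float(vals.min()),
        "STD": std,
        "Variance": var,
        "Smoothness": 1.0 - 1.0 / (1.0 + var),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Entropy": entropy,
    }


def _quantize_patch(patch: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = float(patch.min()), float(patch.max())
    if hi == lo:
        return np.zeros(patch.shape, dtype=np.uint8)
    q = np.floor((patch - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_features(
    roi: ROI, pixels: np.ndarray, spec: GlcmSpec | None = None
) -> tuple[dict[str, float], list[str]]:
    """72 GLCM values on the ROI's bounding-box patch.

    Returns the name->value map plus the list of offset tags whose patch was
    smaller than the offset and therefore computed on a zero-padded patch
    (flagged, per the degenerate-input contract).
    """
    spec = spec or GlcmSpec()
    rs, cs = roi.patch_slices()
    patch = np.asarray(pixels[rs, cs], dtype=float)
    q = _quantize_patch(patch, spec.gray_levels)
    constant = patch.max() == patch.min()
    angles = [math.radians(a) for a in spec.angles_deg]
    out: dict[str, float] = {}
    flagged: list[str] = []
    for i, dist in enumerate(spec.offsets):
        tag = spec.offset_tag(i)
        qi = q
        if min(q.shape) <= dist:
            pad_r = max(0, dist + 1 - q.shape[0])
            pad_c = max(0, dist + 1 - q.shape[1])
            qi = np.pad(q, ((0, pad_r), (0, pad_c)))
            flagged.append(tag)
        glcm = graycomatrix(
            qi, distances=[dist], angles=angles,
            levels=spec.gray_levels, symmetric=True, normed=True,
        )
        for base in GLCM_BASES:
            vals = graycoprops(glcm, base.lower())[0]  # 4 angles
            if base == "Correlation" and constant:
                vals = np.zeros(4)  # degenerate-variance rule
            for a_deg, v in zip(spec.angles_deg, vals):
                out[f"{base} {a_deg} {tag}"] = float(v)
            out[f"{base} Mean {tag}"] = float(np.mean(vals))
            out[f"{base} STD {tag}"] = float(np.std(vals))
    return out, flagged


def assemble_feature_vector(
    roi: ROI,
    pixels: np.ndarray,
    age: float,
    birads_density: str,
    spec: GlcmSpec | None = None,
) -> FeatureVector:
    """15 shape + 9 intensity/FOS + 72 GLCM + 2 epidemiological = 98 values."""
    if birads_density not in DENSITY_CODES:
        raise ValueError(f"unknown BI-RADS density {birads_density!r}")
    values = {}
    values.update(shape_features(roi))
    values.update(intensity_fos_features(roi, pixels))
    glcm, _ = glcm_features(roi, pixels, spec)
    values.update(glcm)
    values["Patient Age"] = float(age)
    values["Breast Density"] = float(DENSITY_CODES[birads_density])
    registry = feature_registry(spec)
    return FeatureVector(values={name: values[name] for name in registry})
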