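"""Core domain types and readers/writers for images, masks, manifests and feature tables.

All images are held internally as ``float64`` grids normalized to [0, 1]
(the original bit depth is kept as metadata). Pixel coordinates are 0-based
``(row, col)`` with the origin at the top-left; annotation masks share the
grid of their paired image exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class View(str, Enum):
    CC = "CC"
    MLO = "MLO"


class Laterality(str, Enum):
    L = "L"
    R = "R"


class Round(str, Enum):
    PRIOR = "prior"
    CURRENT = "current"
    FUTURE = "future"


class MaskSource(str, Enum):
    EXPERT = "expert"
    PROPAGATED = "propagated"
    SYNTHETIC = "synthetic"


class CaseLabel(str, Enum):
    NORMAL = "normal"
    MALIGNANT = "malignant"


#: BI-RADS density categories, ordinal-encoded a..d -> 1..4.
DENSITY_CODES = {"a": 1, "b": 2, "c": 3, "d": 4}


@dataclass
class Mammogram:
    """A single mammographic view: 2-D intensity grid plus acquisition metadata.

    ``pixels`` is float64 in [0, 1]; ``bit_depth`` records the integer depth
    of the source file so a lossless round trip is possible.
    """

    pixels: np.ndarray
    view: View
    round: Round
    patient_id: str
    laterality: Laterality = Laterality.L
    bit_depth: int = 16
    spacing: float | None = None  # mm / pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Mammogram pixels must be a 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Mammogram pixels must be finite")
        if self.pixels.min() < 0:
            raise ValueError("Mammogram pixels must be non-negative")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        self.view = View(self.view)
        self.round = Round(self.round)
        self.laterality = Laterality(self.laterality)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Mammogram":
        """Copy of this mammogram carrying new pixel data (same metadata)."""
        return Mammogram(
            pixels=pixels,
            view=self.view,
            round=self.round,
            patient_id=self.patient_id,
            laterality=self.laterality,
            bit_depth=self.bit_depth,
            spacing=self.spacing,
        )


@dataclass
class AnnotationMask:
    """Binary mask on the grid of a paired mammogram."""

    pixels: np.ndarray
    source: MaskSource = MaskSource.EXPERT

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be in {0, 1}")
        self.pixels = arr.astype(bool)
        self.source = MaskSource(self.source)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def is_empty(self) -> bool:
        return not bool(self.pixels.any())

    def labeled_components(self) -> np.ndarray:
        """Connected-component labeling (8-connectivity) of the union mask."""
        from scipy import ndimage

        labels, _ = ndimage.label(self.pixels, structure=np.ones((3, 3)))
        return labels


@dataclass
class CaseRecord:
    """One patient: six images (3 rounds x 2 views), metadata, and — for
    malignant cases — the expert annotation of each future-round mass."""

    patient_id: str
    age: float
    birads_density: str
    label: CaseLabel
    images: dict[tuple[Round, View], Mammogram] = field(default_factory=dict)
    future_masks: dict[View, AnnotationMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label = CaseLabel(self.label)
        if self.birads_density not in DENSITY_CODES:
            raise ValueError(f"unknown BI-RADS density {self.birads_density!r}")

    def validate(self) -> None:
        expected = [(r, v) for r in Round for v in View]
        missing = [slot for slot in expected if slot not in self.images]
        if missing:
            raise ValueError(
                f"case {self.patient_id}: missing image slots {missing}"
            )
        if self.label is CaseLabel.MALIGNANT and not self.future_masks:
            raise ValueError(
                f"malignant case {self.patient_id} has no future mass annotation"
            )
        if self.label is CaseLabel.NORMAL and self.future_masks:
            raise ValueError(
                f"normal case {self.patient_id} must not carry future masks"
            )
        for (rnd, view), img in self.images.items():
            if img.round is not rnd or img.view is not view:
                raise ValueError(
                    f"case {self.patient_id}: image metadata disagrees with slot "
                    f"({rnd.value}, {view.value})"
                )
        for view, mask in self.future_masks.items():
            img = self.images.get((Round.FUTURE, View(view)))
            if img is not None and mask.shape != img.shape:
                raise ValueError(
                    f"case {self.patient_id}: future mask shape {mask.shape} "
                    f"!= image shape {img.shape} for view {view}"
                )


@dataclass
class CohortManifest:
    """An ordered collection of cases with unique patient ids."""

    cases: list[CaseRecord]

    def __post_init__(self) -> None:
        ids = [c.patient_id for c in self.cases]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s): {dupes}")
        # canonical order so manifest contents are permutation-invariant
        self.cases = sorted(self.cases, key=lambda c: c.patient_id)

    @property
    def counts(self) -> dict[str, int]:
        out = {"total": len(self.cases)}
        for lab in CaseLabel:
            out[lab.value] = sum(1 for c in self.cases if c.label is lab)
        return out

    def __len__(self) -> int:
        return len(self.cases)

    def malignant_cases(self) -> list[CaseRecord]:
        return [c for c in self.cases if c.label is CaseLabel.MALIGNANT]


# ---------------------------------------------------------------------------
# image I/O


def _read_pixel_array(path: Path) -> tuple[np.ndarray, int]:
    """Read a single-channel image file; return (integer array, bit depth)."""
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        depth = int(getattr(ds, "BitsAllocated", 16))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
        depth = 8 if arr.dtype == np.uint8 else 16
    if arr.ndim != 2:
        raise ValueError(f"{path}: single-channel required (got shape {arr.shape})")
    return np.asarray(arr), depth


def load_mammogram(
    path: str | Path,
    *,
    view: View | str,
    round: Round | str,
    patient_id: str,
    laterality: Laterality | str = Laterality.L,
    spacing: float | None = None,
) -> Mammogram:
    """Load a DICOM/PNG/TIFF mammogram, normalizing pixels to [0, 1].

    Intensities are divided by ``2**bit_depth - 1`` so the original integer
    grid is recoverable exactly (lossless round trip).
    """
    path = Path(path)
    arr, depth = _read_pixel_array(path)
    scale = float(2**depth - 1)
    return Mammogram(
        pixels=arr.astype(np.float64) / scale,
        view=View(view),
        round=Round(round),
        patient_id=patient_id,
        laterality=Laterality(laterality),
        bit_depth=depth,
        spacing=spacing,
    )


def save_mammogram(img: Mammogram, path: str | Path) -> None:
    """Write a mammogram as an integer PNG/TIFF at its recorded bit depth."""
    import imageio.v3 as iio

    scale = 2**img.bit_depth - 1
    arr = np.clip(np.rint(img.pixels * scale), 0, scale)
    dtype = np.uint8 if img.bit_depth <= 8 else np.uint16
    iio.imwrite(str(Path(path)), arr.astype(dtype))


def load_mask(path: str | Path, source: MaskSource | str = MaskSource.EXPERT) -> AnnotationMask:
    import imageio.v3 as iio

    arr = iio.imread(str(Path(path)))
    if arr.ndim != 2:
        raise ValueError(f"{path}: single-channel mask required")
    return AnnotationMask(pixels=(arr > 0).astype(np.uint8), source=MaskSource(source))


def save_mask(mask: AnnotationMask, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(Path(path)), (mask.pixels.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# manifest I/O

_ROUND_KEYS = [r.value for r in Round]
_VIEW_KEYS = [v.value for v in View]


def load_manifest(path: str | Path) -> CohortManifest:
    """Load a JSON cohort manifest and every image/mask it references.

    The JSON layout is::

        {"cases": [{"patient_id": ..., "age": ..., "birads_density": ...,
                    "label": ..., "images": {"prior": {"CC": "p.png", ...}, ...},
                    "future_masks": {"CC": "m.png", ...}}, ...]}

    Relative paths resolve against the manifest's directory. Every loaded
    case is validated against its invariants.
    """
    path = Path(path)
    root = path.parent
    spec = json.loads(path.read_text())
    cases = []
    for entry in spec["cases"]:
        pid = entry["patient_id"]
        images: dict[tuple[Round, View], Mammogram] = {}
        for rnd in _ROUND_KEYS:
            for view in _VIEW_KEYS:
                rel = entry["images"].get(rnd, {}).get(view)
                if rel is None:
                    continue
                images[(Round(rnd), View(view))] = load_mammogram(
                    root / rel, view=view, round=rnd, patient_id=pid,
                    laterality=entry.get("laterality", "L"),
                )
        masks = {
            View(v): load_mask(root / rel, source=MaskSource.EXPERT)
            for v, rel in entry.get("future_masks", {}).items()
        }
        case = CaseRecord(
            patient_id=pid,
            age=float(entry["age"]),
            birads_density=entry["birads_density"],
            label=CaseLabel(entry["label"]),
            images=images,
            future_masks=masks,
        )
        case.validate()
        cases.append(case)
    return CohortManifest(cases=cases)


# ---------------------------------------------------------------------------
# feature tables

#: columns that accompany the feature values in every table
META_COLUMNS = ["patient_id", "view", "roi_id", "label"]


def write_feature_table(rows: list[dict], path: str | Path, feature_names: list[str]) -> None:
    """Write ROI feature rows to CSV: feature columns + patient/view/roi/label.

    Every row must carry exactly the registry's feature names; values are
    written with ``repr`` round-trip precision.
    """
    for row in rows:
        extra = set(row["features"]) ^ set(feature_names)
        if extra:
            raise ValueError(f"inconsistent feature registry, mismatch: {sorted(extra)}")
    records = []
    for row in rows:
        rec = {k: row[k] for k in META_COLUMNS}
        rec.update({name: row["features"][name] for name in feature_names})
        records.append(rec)
    df = pd.DataFrame(records, columns=META_COLUMNS + list(feature_names))
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # the default (fast) float parser can be one ulp off; exact re-read matters
    # for the lossless round-trip contract
    return pd.read_csv(path, float_precision="round_trip")
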