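"""Reproducible synthetic mammogram triplets emulating the study cohort.

Real screening data with three consecutive rounds, expert mass outlines and
biopsy confirmation are private; this module generates a stand-in cohort
with the same structure so that every pipeline stage is testable end to end:

* 75 patients by default, 34 malignant / 41 normal, two views (CC, MLO),
  three rounds (prior, current, future);
* a breast-shaped support (half-ellipse; MLO adds a pectoral wedge) filled
  with multi-scale smooth background texture;
* rounds related by smooth random deformation fields (compression and
  positioning differences between visits) plus per-round noise and clutter
  blobs that appear/disappear between rounds (benign interval change);
* malignant cases receive a bright mass in the future round and a faint
  precursor (default 0.15 of the intensity range — visible to subtraction,
  near-invisible to the eye) at the deformation-consistent location in the
  current round. The exact injected future-mass support is the expert-style
  annotation; the injected current-round precursor disk is kept as generator
  truth for validating ground-truth propagation.

All randomness flows from the single config seed. The generator emulates
geometry, texture and interval change — not X-ray physics, scatter, dose or
vendor post-processing; performance on it bounds pipeline correctness, not
clinical accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_model_io import (
    AnnotationMask,
    CaseLabel,
    CaseRecord,
    CohortManifest,
    Mammogram,
    MaskSource,
    Round,
    View,
    save_mammogram,
    save_mask,
)
from .registration import DeformationField, warp_array

#: BI-RADS density counts of the study population (a, b, c, d)
DENSITY_COUNTS = (13, 29, 29, 4)
AGE_RANGE = (46.0, 79.0)


@dataclass
class SyntheticConfig:
    n_patients: int = 75
    malignant_fraction: float = 34 / 75
    image_shape: tuple[int, int] = (256, 256)
    texture_scale: float = 1.0
    deformation_amplitude: float = 8.0
    deformation_smoothness: float = 40.0
    mass_radius_range: tuple[float, float] = (9.0, 15.0)
    mass_contrast: float = 0.4
    precursor_contrast: float = 0.15
    clutter_rate: float = 90.0
    clutter_radius_range: tuple[float, float] = (4.0, 6.5)
    clutter_contrast_range: tuple[float, float] = (0.15, 0.28)
    clutter_min_separation: float = 24.0
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.malignant_fraction < 1.0):
            raise ValueError("malignant_fraction must lie in (0, 1)")
        if self.deformation_amplitude < 0:
            raise ValueError("deformation amplitude must be >= 0")


@dataclass
class CaseTruth:
    """Generator-side ground truth for one malignant case/view."""

    current_center: tuple[float, float]
    future_center: tuple[float, float]
    radius: float
    current_mask: np.ndarray  # precursor support on the current grid


# ---------------------------------------------------------------------------
# geometry and texture


def breast_support(shape: tuple[int, int], view: View) -> np.ndarray:
    """Half-ellipse breast footprint with the chest wall at column 0; the
    MLO view adds a pectoral wedge in the upper corner."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    a = 0.42 * rows
    b = 0.80 * cols
    ell = ((rr - rows / 2.0) / a) ** 2 + (cc / b) ** 2 <= 1.0
    if view is View.MLO:
        wedge = (rr + 1.5 * cc) < 0.55 * rows
        ell = ell | (wedge & (cc < 0.35 * cols))
    return ell


def _multiscale_texture(shape: tuple[int, int], rng: np.random.Generator, scale: float) -> np.ndarray:
    tex = np.zeros(shape)
    for sigma, w in ((4.0, 0.5), (8.0, 0.3), (16.0, 0.2)):
        layer = ndimage.gaussian_filter(rng.normal(size=shape), sigma * scale)
        layer /= np.abs(layer).max() + 1e-12
        tex += w * layer
    tex -= tex.min()
    tex /= tex.max() + 1e-12
    return tex


def smooth_deformation(
    shape: tuple[int, int],
    amplitude: float,
    smoothness: float,
    rng: np.random.Generator,
) -> DeformationField:
    """Gaussian-smoothed random vector field with max magnitude = amplitude."""
    d = rng.normal(size=(*shape, 2))
    for k in range(2):
        d[..., k] = ndimage.gaussian_filter(d[..., k], smoothness)
    mag = np.hypot(d[..., 0], d[..., 1])
    peak = mag.max()
    if peak > 0 and amplitude > 0:
        d *= amplitude / peak
    else:
        d[:] = 0.0
    return DeformationField(d, shape)


def _soft_disk(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    plateau: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(soft intensity profile in [0,1], hard boolean support) of a disk.

    ``plateau < 1`` flattens the profile top (``(1-(d/r)^2)**plateau``):
    masses are dense lumps with a defined border, whereas benign interval
    changes taper off smoothly.
    """
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dist = np.hypot(rr - center[0], cc - center[1])
    hard = dist <= radius
    soft = np.clip(1.0 - (dist / radius) ** 2, 0.0, 1.0) ** plateau
    return soft, hard


def _scatter_clutter(
    base: np.ndarray,
    support: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add Poisson-distributed benign change blobs inside the breast interior.

    Blob count is Poisson(clutter_rate); placement is dart-throwing with a
    minimum separation so distinct interval changes stay distinct ROIs
    rather than fusing under the 10-px morphological closing.
    """
    out = base.copy()
    interior = ndimage.binary_erosion(support, iterations=16)
    rows_i, cols_i = np.nonzero(interior)
    if rows_i.size == 0:
        return out
    n = rng.poisson(cfg.clutter_rate)
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < n and attempts < 30 * n:
        attempts += 1
        j = rng.integers(0, rows_i.size)
        center = (float(rows_i[j]), float(cols_i[j]))
        if any(
            np.hypot(center[0] - p[0], center[1] - p[1]) < cfg.clutter_min_separation
            for p in placed
        ):
            continue
        placed.append(center)
        radius = rng.uniform(*cfg.clutter_radius_range)
        contrast = rng.uniform(*cfg.clutter_contrast_range)
        soft, _ = _soft_disk(base.shape, center, radius)
        out += contrast * soft
    return out


def _solve_future_center(
    center: tuple[float, float], fld: DeformationField, iters: int = 10
) -> tuple[float, float]:
    """Find x with x + d(x) = center (where the current-round point lands in
    the future round under backward warping) by fixed-point iteration."""
    rows, cols = fld.fixed_shape
    x = np.array(center, dtype=float)
    for _ in range(iters):
        ri = int(np.clip(round(x[0]), 0, rows - 1))
        ci = int(np.clip(round(x[1]), 0, cols - 1))
        x = np.array(center) - fld.displacements[ri, ci]
    return float(x[0]), float(x[1])


# ---------------------------------------------------------------------------
# case and cohort generation


def _case_ids(config: SyntheticConfig) -> list[tuple[str, CaseLabel]]:
    n_mal = round(config.malignant_fraction * config.n_patients)
    out = []
    for i in range(config.n_patients):
        label = CaseLabel.MALIGNANT if i < n_mal else CaseLabel.NORMAL
        out.append((f"P{i:03d}", label))
    return out


def generate_case(
    config: SyntheticConfig, patient_index: int
) -> tuple[CaseRecord, dict[View, CaseTruth]]:
    """Generate one patient: six images, masks, and generator truth.

    Deterministic in (config.seed, patient_index): the same pair always
    yields a bitwise-identical case.
    """
    ids = _case_ids(config)
    if not (0 <= patient_index < len(ids)):
        raise ValueError("patient_index out of range")
    pid, label = ids[patient_index]
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, patient_index])
    )
    age = float(rng.uniform(*AGE_RANGE))
    density = rng.choice(
        ["a", "b", "c", "d"], p=np.array(DENSITY_COUNTS) / sum(DENSITY_COUNTS)
    )
    shape = tuple(config.image_shape)
    images: dict[tuple[Round, View], Mammogram] = {}
    masks: dict[View, AnnotationMask] = {}
    truths: dict[View, CaseTruth] = {}

    for view in View:
        support = breast_support(shape, view)
        tex = _multiscale_texture(shape, rng, config.texture_scale)
        base = np.where(support, 0.25 + 0.5 * tex, 0.0)

        d_prior = smooth_deformation(
            shape, config.deformation_amplitude, config.deformation_smoothness, rng
        )
        d_future = smooth_deformation(
            shape, config.deformation_amplitude, config.deformation_smoothness, rng
        )

        mass_center = None
        radius = None
        precursor_mask = None
        if label is CaseLabel.MALIGNANT:
            # keep mass centers away from the breast border by roughly the
            # largest mass radius plus the periphery band (scaled down on
            # small grids so smoke-scale cohorts remain generable)
            margin = min(
                35,
                max(1, min(shape) // 2 - int(config.mass_radius_range[1]) - 2),
            )
            interior = ndimage.binary_erosion(support, iterations=margin)
            rows_i, cols_i = np.nonzero(interior)
            if rows_i.size == 0:
                raise ValueError("mass radius exceeds breast support")
            j = rng.integers(0, rows_i.size)
            mass_center = (float(rows_i[j]), float(cols_i[j]))
            radius = float(rng.uniform(*config.mass_radius_range))
            if radius >= 35:
                raise ValueError("mass radius exceeds breast support margin")

        round_pixels: dict[Round, np.ndarray] = {}
        # current round is the reference frame
        cur = base.copy()
        if mass_center is not None:
            soft, hard = _soft_disk(shape, mass_center, radius, plateau=0.4)
            cur = cur + config.precursor_contrast * soft
            precursor_mask = hard
        round_pixels[Round.CURRENT] = cur

        prior = warp_array(base, d_prior, order=1)
        round_pixels[Round.PRIOR] = prior

        fut = warp_array(base, d_future, order=1)
        future_center = None
        if mass_center is not None:
            future_center = _solve_future_center(mass_center, d_future)
            soft_f, hard_f = _soft_disk(shape, future_center, radius, plateau=0.4)
            fut = fut + config.mass_contrast * soft_f
            masks[view] = AnnotationMask(
                pixels=hard_f.astype(np.uint8), source=MaskSource.SYNTHETIC
            )
            truths[view] = CaseTruth(
                current_center=mass_center,
                future_center=future_center,
                radius=radius,
                current_mask=precursor_mask,
            )
        round_pixels[Round.FUTURE] = fut

        for rnd, px in round_pixels.items():
            px = _scatter_clutter(px, support, config, rng)
            px = px + rng.normal(scale=config.noise_sigma, size=shape)
            px = np.clip(px, 0.0, 1.0)
            images[(rnd, view)] = Mammogram(
                pixels=px, view=view, round=rnd, patient_id=pid,
                bit_depth=16,
            )

    case = CaseRecord(
        patient_id=pid, age=age, birads_density=str(density),
        label=label, images=images, future_masks=masks,
    )
    case.validate()
    return case, truths


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[CohortManifest, dict[str, dict[View, CaseTruth]]]:
    """Generate the full in-memory cohort and its generator truth."""
    config = config or SyntheticConfig()
    cases = []
    truths: dict[str, dict[View, CaseTruth]] = {}
    for i in range(config.n_patients):
        case, truth = generate_case(config, i)
        cases.append(case)
        if truth:
            truths[case.patient_id] = truth
    return CohortManifest(cases=cases), truths


def write_cohort(
    config: SyntheticConfig,
    out_dir: str | Path,
) -> Path:
    """Generate the cohort and write PNG images, PNG masks and the JSON
    manifest consumable by ``data_model_io.load_manifest``.

    Generator-truth precursor masks are written alongside with a
    ``synthetic_truth`` prefix (they are a synthetic stand-in for what, on
    clinical data, only Part A can estimate). Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest, truths = generate_cohort(config)
    entries = []
    for case in manifest.cases:
        case_dir = out_dir / case.patient_id
        case_dir.mkdir(exist_ok=True)
        img_paths: dict[str, dict[str, str]] = {}
        for (rnd, view), img in case.images.items():
            rel = f"{case.patient_id}/{rnd.value}_{view.value}.png"
            save_mammogram(img, out_dir / rel)
            img_paths.setdefault(rnd.value, {})[view.value] = rel
        mask_paths = {}
        for view, mask in case.future_masks.items():
            rel = f"{case.patient_id}/future_mask_{view.value}.png"
            save_mask(mask, out_dir / rel)
            mask_paths[view.value] = rel
        for view, truth in truths.get(case.patient_id, {}).items():
            rel = f"{case.patient_id}/synthetic_truth_current_{view.value}.png"
            save_mask(
                AnnotationMask(truth.current_mask.astype(np.uint8), MaskSource.SYNTHETIC),
                out_dir / rel,
            )
        entries.append(
            {
                "patient_id": case.patient_id,
                "age": case.age,
                "birads_density": case.birads_density,
                "label": case.label.value,
                "images": img_paths,
                "future_masks": mask_paths,
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"cases": entries}, indent=1))
    return manifest_path
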