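"""End-to-end orchestration of ground-truth localization (Part A) and the
prediction pipeline (Part B).

Part A: for each malignant case and view, preprocess the future and current
images, register future -> current (current fixed), and propagate the
future-round mass annotation onto the current grid. The future images play
no further role.

Part B: for every case and view, preprocess prior and current, register
prior -> current, subtract, enhance, segment candidate ROIs, label them
against the propagated masks, extract the 98-feature vectors, and evaluate
a classifier under patient-grouped cross-validation.

Failures are isolated per case (logged and skipped), not fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify_eval import (
    ClassifierSpec,
    CVScheme,
    EnsembleSpec,
    EvaluationReport,
    FoldArtifacts,
    default_ensemble_spec,
    run_cv,
)
from .data_model_io import (
    AnnotationMask,
    CaseLabel,
    CaseRecord,
    CohortManifest,
    Round,
    View,
)
from .features import GlcmSpec, assemble_feature_vector, feature_registry
from .preprocess import PreprocessConfig, preprocess_image, segment_breast
from .registration import DemonsConfig, demons_register, propagate_future_mask, warp_image
from .segmentation import (
    SegmentationConfig,
    assign_gt_labels,
    segment_image,
    select_threshold,
)
from .selection import reference_subset
from .subtraction import SubtractionImage, temporal_subtract, unsharp_enhance

log = logging.getLogger("mammodelta")


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    demons: DemonsConfig = field(default_factory=DemonsConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    glcm: GlcmSpec = field(default_factory=GlcmSpec)
    unsharp_radius: float = 5.0
    unsharp_amount: float = 1.0
    clip_negative: bool = True
    # "fixed" uses the published 14-feature subset; "per_fold" refits the
    # majority-rule selection inside each training fold
    selection_mode: str = "fixed"
    run_id: str = "run0"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        """Build a config from a JSON file of nested module parameters.

        Top-level keys mirror the module names (``preprocess``, ``demons``,
        ``segmentation``, ``glcm``) plus the scalar pipeline settings;
        unknown keys raise.
        """
        import json
        from pathlib import Path

        raw = json.loads(Path(path).read_text())
        nested = {
            "preprocess": PreprocessConfig,
            "demons": DemonsConfig,
            "segmentation": SegmentationConfig,
            "glcm": GlcmSpec,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested:
                if "clahe_tiles" in value:
                    value["clahe_tiles"] = tuple(value["clahe_tiles"])
                for tup in ("offsets", "angles_deg", "candidate_percentiles"):
                    if tup in value:
                        value[tup] = tuple(value[tup])
                kwargs[key] = nested[key](**value)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**kwargs)


def run_part_a(
    manifest: CohortManifest, config: PipelineConfig | None = None
) -> dict[tuple[str, str], AnnotationMask]:
    """Propagated ground-truth masks, keyed by (patient_id, view)."""
    config = config or PipelineConfig()
    out: dict[tuple[str, str], AnnotationMask] = {}
    for case in manifest.malignant_cases():
        for view, future_mask in case.future_masks.items():
            try:
                current = preprocess_image(
                    case.images[(Round.CURRENT, view)], config.preprocess
                )
                future = preprocess_image(
                    case.images[(Round.FUTURE, view)], config.preprocess
                )
                fld = demons_register(current, future, config.demons)
                out[(case.patient_id, view.value)] = propagate_future_mask(
                    future_mask, fld
                )
            except Exception:
                log.exception(
                    "Part A failed for %s/%s; case skipped",
                    case.patient_id, view.value,
                )
    return out


@dataclass
class ViewArtifacts:
    """Intermediates of one case/view in Part B."""

    patient_id: str
    view: str
    subtraction: SubtractionImage
    breast_mask: AnnotationMask
    gt_mask: AnnotationMask | None


def _subtract_view(
    case: CaseRecord,
    view: View,
    gt_masks: dict[tuple[str, str], AnnotationMask],
    config: PipelineConfig,
) -> ViewArtifacts:
    current = preprocess_image(case.images[(Round.CURRENT, view)], config.preprocess)
    prior = preprocess_image(case.images[(Round.PRIOR, view)], config.preprocess)
    fld = demons_register(current, prior, config.demons)
    prior_reg = warp_image(prior, fld)
    diff = temporal_subtract(current, prior_reg, clip_negative=config.clip_negative)
    diff = unsharp_enhance(diff, config.unsharp_radius, config.unsharp_amount)
    diff.pixels = np.clip(diff.pixels, 0.0, 1.0)
    breast = segment_breast(current)
    gt = gt_masks.get((case.patient_id, view.value))
    return ViewArtifacts(
        patient_id=case.patient_id, view=view.value,
        subtraction=diff, breast_mask=breast, gt_mask=gt,
    )


def build_feature_table(
    manifest: CohortManifest,
    gt_masks: dict[tuple[str, str], AnnotationMask],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Subtract, segment and featurize every case/view into one ROI table.

    The segmentation threshold is taken from the config when numeric;
    ``"auto"`` selects it by histogram analysis and optimization of the
    ground-truth recovery rate over the cohort's subtraction images (the
    training-time calibration step of the workflow).
    """
    config = config or PipelineConfig()
    artifacts: list[ViewArtifacts] = []
    n_failed = 0
    for case in manifest.cases:
        for view in View:
            try:
                artifacts.append(_subtract_view(case, view, gt_masks, config))
            except Exception:
                n_failed += 1
                log.exception("Part B failed for %s/%s", case.patient_id, view.value)
    if n_failed:
        log.warning("%d case/views failed and were excluded", n_failed)

    seg = config.segmentation
    if seg.threshold == "auto":
        threshold = select_threshold(
            [a.subtraction for a in artifacts],
            [a.gt_mask for a in artifacts],
            [a.breast_mask for a in artifacts],
            seg,
        )
    else:
        threshold = float(seg.threshold)

    registry = feature_registry(config.glcm)
    meta = {c.patient_id: c for c in manifest.cases}
    rows = []
    for art in artifacts:
        rois = segment_image(art.subtraction, art.breast_mask, threshold, seg)
        rois = assign_gt_labels(rois, art.gt_mask, seg.overlap_fraction)
        case = meta[art.patient_id]
        for roi in rois:
            fv = assemble_feature_vector(
                roi, art.subtraction.pixels, case.age, case.birads_density,
                config.glcm,
            )
            row = {
                "patient_id": art.patient_id,
                "view": art.view,
                "roi_id": roi.roi_id,
                "label": int(roi.gt_label == "future_malignant"),
            }
            row.update({name: fv.values[name] for name in registry})
            rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "view", "roi_id", "label"] + registry)


def run_part_b(
    manifest: CohortManifest,
    gt_masks: dict[tuple[str, str], AnnotationMask],
    config: PipelineConfig | None = None,
    scheme: CVScheme | None = None,
    spec: ClassifierSpec | EnsembleSpec | None = None,
    seed: int = 0,
) -> tuple[EvaluationReport, pd.DataFrame, list[FoldArtifacts]]:
    """Full Part B: feature table plus grouped-CV evaluation."""
    config = config or PipelineConfig()
    scheme = scheme or CVScheme(kind="lopo")
    spec = spec or default_ensemble_spec(seed)
    table = build_feature_table(manifest, gt_masks, config)
    report, folds = run_cv(
        table, scheme, spec, feature_subset=_subset_for(config, table), seed=seed,
        selection_mode="fixed" if config.selection_mode == "fixed" else "per_fold",
    )
    return report, table, folds


def _subset_for(config: PipelineConfig, table: pd.DataFrame) -> list[str] | None:
    if config.selection_mode == "fixed":
        return reference_subset().names
    return None
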