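"""Model/Results facade over the ROI classification stage.

``MassEmergenceModel`` is built from a ROI feature table (or straight from a
cohort manifest, in which case the imaging pipeline runs first); ``fit()``
performs patient-grouped cross-validation and returns a
``MassEmergenceResults`` carrying the pooled confusion counts, the derived
metrics, per-ROI out-of-fold predictions and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify_eval import (
    ClassifierSpec,
    CVScheme,
    EnsembleSpec,
    EvaluationReport,
    FoldArtifacts,
    default_ensemble_spec,
    mcnemar_test,
    run_cv,
)
from .selection import reference_subset


class MassEmergenceModel:
    """Predicts which subtraction-image ROIs will develop into a mass.

    Parameters
    ----------
    table:
        ROI feature table with ``patient_id``, ``view``, ``roi_id``,
        ``label`` columns plus feature columns (the output of
        ``pipeline.build_feature_table`` or a CSV read back through
        ``data_model_io.read_feature_table``).
    feature_subset:
        Feature names to classify on. Default: the 14-feature
        majority-rule reference subset.
    """

    def __init__(self, table: pd.DataFrame, feature_subset: list[str] | None = None):
        required = {"patient_id", "view", "roi_id", "label"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table lacks required columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.feature_subset = (
            feature_subset if feature_subset is not None else reference_subset().names
        )

    @classmethod
    def from_feature_table(cls, path, feature_subset: list[str] | None = None) -> "MassEmergenceModel":
        from .data_model_io import read_feature_table

        return cls(read_feature_table(path), feature_subset)

    @classmethod
    def from_manifest(
        cls, manifest, config=None, feature_subset: list[str] | None = None
    ) -> "MassEmergenceModel":
        """Run Part A + the Part B imaging stages, then build the model."""
        from .pipeline import PipelineConfig, build_feature_table, run_part_a

        config = config or PipelineConfig()
        gt = run_part_a(manifest, config)
        table = build_feature_table(manifest, gt, config)
        return cls(table, feature_subset)

    def fit(
        self,
        classifier: str | ClassifierSpec | EnsembleSpec = "ensemble_voting",
        cv: str = "lopo",
        k: int = 5,
        seed: int = 0,
        selection_mode: str = "fixed",
    ) -> "MassEmergenceResults":
        spec: ClassifierSpec | EnsembleSpec
        if isinstance(spec_in := classifier, (ClassifierSpec, EnsembleSpec)):
            spec = spec_in
        elif classifier == "ensemble_voting":
            spec = default_ensemble_spec(seed)
        else:
            spec = ClassifierSpec(classifier, seed=seed)
        scheme = CVScheme(kind=cv, k=k)
        report, folds = run_cv(
            self.table,
            scheme,
            spec,
            feature_subset=self.feature_subset if selection_mode == "fixed" else None,
            seed=seed,
            selection_mode=selection_mode,
        )
        return MassEmergenceResults(self, spec, scheme, report, folds)


@dataclass
class MassEmergenceResults:
    model: MassEmergenceModel
    spec: ClassifierSpec | EnsembleSpec
    scheme: CVScheme
    report: EvaluationReport
    folds: list[FoldArtifacts]

    @property
    def predictions(self) -> pd.DataFrame:
        """Pooled out-of-fold per-ROI predictions."""
        return self.report.fold_predictions

    def summary(self) -> str:
        r = self.report
        name = (
            f"ensemble ({self.spec.voting} voting, {len(self.spec.members)} members)"
            if isinstance(self.spec, EnsembleSpec)
            else self.spec.family
        )
        lines = [
            "Mass emergence prediction — patient-grouped cross-validation",
            "=" * 62,
            f"Classifier:       {name}",
            f"CV scheme:        {self.scheme.kind}"
            + (f" (k={self.scheme.k})" if self.scheme.kind == "kfold" else ""),
            f"ROIs:             {r.tp + r.fn + r.tn + r.fp}"
            f"  (future malignant: {r.tp + r.fn})",
            "-" * 62,
            f"Sensitivity:      {r.tp}/{r.tp + r.fn}  {r.sensitivity:.2f}%",
            f"Specificity:      {r.tn}/{r.tn + r.fp}  {r.specificity:.2f}%",
            f"Accuracy:         {r.tp + r.tn}/{r.tp + r.fn + r.tn + r.fp}  {r.accuracy:.2f}%",
            f"AUC:              {r.auc:.2f}",
            f"FP per image:     {r.fp_per_image:.2f}",
            f"Patient-level sensitivity: {100 * r.per_patient_sensitivity:.1f}%",
            "=" * 62,
        ]
        return "\n".join(lines)

    def compare(self, other: "MassEmergenceResults") -> tuple[float, float]:
        """McNemar test against another fitted result on the same ROIs."""
        a = self.predictions.sort_values(["patient_id", "view", "roi_id"])
        b = other.predictions.sort_values(["patient_id", "view", "roi_id"])
        if not (a["roi_id"].to_numpy() == b["roi_id"].to_numpy()).all():
            raise ValueError("results were computed on different ROI sets")
        return mcnemar_test(
            a["pred"].to_numpy(), b["pred"].to_numpy(), a["label"].to_numpy()
        )
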