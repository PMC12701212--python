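"""Class balancing, classifiers, patient-grouped cross-validation, metrics,
and paired statistical comparison.

Leakage rules: within every cross-validation fold the scaler, the ADASYN
oversampler and (in per-fold mode) the feature selection are fitted on the
training patients only; test patients are never resampled or used to fit
anything. Folds are built per patient, so no patient contributes ROIs to
both sides of a split.

Classifier ranking convention follows a sensitivity-first rationale: soft
votes threshold at 0.5 and hard-vote ties resolve to the positive (future
malignant) class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

CLASSIFIER_FAMILIES = (
    "random_forest",
    "gradient_boosting",
    "mlp",
    "knn",
    "adaboost",
    "svm",
    "naive_bayes",
    "ann",
    "lda",
    "qda",
    "extra_trees",
    "ensemble_voting",
)

KNN_ALLOWED_K = (1, 3, 5, 7, 9, 11)
SVM_ALLOWED_KERNELS = ("linear", "poly", "rbf")


@dataclass
class ClassifierSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "knn":
            k = self.hyperparams.get("k", 9)
            if k not in KNN_ALLOWED_K:
                raise ValueError(f"knn k must be one of {KNN_ALLOWED_K}")
        if self.family == "svm":
            kernel = self.hyperparams.get("kernel", "poly")
            if kernel == "polynomial":
                self.hyperparams["kernel"] = "poly"
            elif kernel not in SVM_ALLOWED_KERNELS:
                raise ValueError(f"svm kernel must be one of {SVM_ALLOWED_KERNELS}")


@dataclass
class EnsembleSpec:
    members: list[ClassifierSpec]
    voting: str = "soft"

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("ensemble needs >= 2 members")
        if self.voting not in ("hard", "soft"):
            raise ValueError("voting must be 'hard' or 'soft'")


def default_ensemble_spec(seed: int = 0) -> EnsembleSpec:
    """Soft voting over LDA, k-NN (k=9), polynomial SVM, naive Bayes and
    extra trees — the best-performing combination under LOPO."""
    return EnsembleSpec(
        members=[
            ClassifierSpec("lda", seed=seed),
            ClassifierSpec("knn", {"k": 9}, seed=seed),
            ClassifierSpec("svm", {"kernel": "poly"}, seed=seed),
            ClassifierSpec("naive_bayes", seed=seed),
            ClassifierSpec("extra_trees", seed=seed),
        ],
        voting="soft",
    )


@dataclass
class CVScheme:
    kind: str = "lopo"  # "lopo" | "kfold"
    k: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("lopo", "kfold"):
            raise ValueError("kind must be 'lopo' or 'kfold'")


@dataclass
class EvaluationReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float  # percent
    specificity: float  # percent
    accuracy: float  # percent
    auc: float
    fp_per_image: float
    per_patient_sensitivity: float
    fold_predictions: pd.DataFrame

    def summary_row(self) -> dict:
        return {
            "Sensitivity [%]": f"{self.tp}/{self.tp + self.fn} {self.sensitivity:.2f}%",
            "Specificity [%]": f"{self.tn}/{self.tn + self.fp} {self.specificity:.2f}%",
            "Accuracy [%]": (
                f"{self.tp + self.tn}/{self.tp + self.fn + self.tn + self.fp} "
                f"{self.accuracy:.2f}%"
            ),
            "AUC": f"{self.auc:.2f}",
        }


# ---------------------------------------------------------------------------
# ADASYN


def adasyn_balance(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 5,
    tol: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive synthetic oversampling of the minority class.

    Synthetic minority samples are allocated per minority point in
    proportion to the fraction of majority points among its k nearest
    neighbors (its local learning difficulty) and generated by linear
    interpolation toward a random minority neighbor. Originals are kept
    unchanged; the output ratio is within ``tol`` of 1:1. If the minority
    class is too small for neighborhood estimates, random duplication is
    used instead (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("adasyn_balance expects a binary problem")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    g = n_maj - n_min
    if g <= tol * n_maj:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    X_min = X[y == minority]

    if n_min <= n_neighbors:
        warnings.warn(
            "minority class too small for ADASYN neighborhoods; "
            "falling back to random duplication",
            stacklevel=2,
        )
        idx = rng.integers(0, n_min, size=g)
        X_new = X_min[idx]
    else:
        # difficulty = majority fraction among k nearest neighbors in X
        nn_all = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
        _, neigh = nn_all.kneighbors(X_min)
        neigh = neigh[:, 1:]
        difficulty = (y[neigh] != minority).mean(axis=1)
        if difficulty.sum() == 0:
            difficulty = np.ones(n_min)
        weights = difficulty / difficulty.sum()
        alloc = rng.multinomial(g, weights)
        nn_min = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n_min)).fit(X_min)
        _, neigh_min = nn_min.kneighbors(X_min)
        neigh_min = neigh_min[:, 1:]
        rows = []
        for i, n_i in enumerate(alloc):
            for _ in range(int(n_i)):
                j = neigh_min[i][rng.integers(0, neigh_min.shape[1])]
                lam = rng.random()
                rows.append(X_min[i] + lam * (X_min[j] - X_min[i]))
        X_new = np.array(rows) if rows else np.empty((0, X.shape[1]))

    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(len(X_new), minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# classifiers


class PlattScaledSVC(BaseEstimator, ClassifierMixin):
    """SVC with probabilities from Platt scaling of the decision function.

    A single SVC fit plus a 1-D logistic regression on its training margins;
    far cheaper than the built-in probability machinery (which refits the
    SVM five times) and sufficient for soft voting.
    """

    def __init__(self, kernel: str = "poly", C: float = 1.0, degree: int = 3, seed: int = 0):
        self.kernel = kernel
        self.C = C
        self.degree = degree
        self.seed = seed

    def fit(self, X, y):
        self.svc_ = SVC(
            kernel=self.kernel, C=self.C, degree=self.degree,
            random_state=self.seed,
        ).fit(X, y)
        self.classes_ = self.svc_.classes_
        margins = self.svc_.decision_function(X).reshape(-1, 1)
        self.platt_ = LogisticRegression(max_iter=1000).fit(margins, y)
        return self

    def predict(self, X):
        return self.svc_.predict(X)

    def predict_proba(self, X):
        margins = self.svc_.decision_function(X).reshape(-1, 1)
        return self.platt_.predict_proba(margins)


def build_classifier(spec: ClassifierSpec):
    """Instantiate the estimator for one classifier family."""
    hp = dict(spec.hyperparams)
    seed = spec.seed
    family = spec.family
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed, n_jobs=1
        )
    if family == "extra_trees":
        return ExtraTreesClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed, n_jobs=1
        )
    if family == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 100), random_state=seed
        )
    if family == "adaboost":
        return AdaBoostClassifier(n_estimators=hp.get("n_estimators", 100), random_state=seed)
    if family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=hp.get("hidden", (100,)),
            random_state=seed, max_iter=300,
        )
    if family == "ann":
        # single hidden layer, ReLU hidden units, softmax-style output,
        # Adam, batch 128, learning rate 1e-4, 100 epochs
        return MLPClassifier(
            hidden_layer_sizes=(hp.get("width", 64),),
            activation="relu",
            solver="adam",
            batch_size=128,
            learning_rate_init=1e-4,
            max_iter=100,
            random_state=seed,
        )
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("k", 9))
    if family == "svm":
        return PlattScaledSVC(
            kernel=hp.get("kernel", "poly"), C=hp.get("C", 1.0),
            degree=hp.get("degree", 3), seed=seed,
        )
    if family == "naive_bayes":
        return GaussianNB()
    if family == "lda":
        return LinearDiscriminantAnalysis()
    if family == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=hp.get("reg_param", 1e-3))
    raise ValueError(f"no single estimator for family {family!r}")


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    """Fit one classifier; features are assumed standardized per fold."""
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training fold")
    est = build_classifier(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return proba[:, pos_col]


def ensemble_predict(
    spec: EnsembleSpec, models: list, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled ensemble scores and labels.

    Soft voting averages member probabilities for the positive class and
    thresholds at 0.5; hard voting takes the majority label with ties going
    to the positive class.
    """
    if spec.voting == "soft":
        scores = np.mean([_positive_proba(m, X) for m in models], axis=0)
        labels = (scores >= 0.5).astype(int)
        return scores, labels
    votes = np.stack([m.predict(X).astype(int) for m in models])
    pos = votes.sum(axis=0)
    labels = (pos >= votes.shape[0] / 2).astype(int)  # tie -> positive
    scores = pos / votes.shape[0]
    return scores, labels


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(
    patient_ids: np.ndarray,
    patient_labels: dict[str, int],
    scheme: CVScheme,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Patient-grouped folds: (train_patients, test_patients) pairs.

    LOPO yields one fold per patient; k-fold shuffles patients with the seed
    and stratifies folds by the patient-level case label.
    """
    patients = np.array(sorted(set(patient_ids)))
    if scheme.kind == "lopo":
        return [
            (patients[patients != p], np.array([p])) for p in patients
        ]
    labels = np.array([patient_labels[p] for p in patients])
    skf = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(patients, labels):
        folds.append((patients[train_idx], patients[test_idx]))
    return folds


@dataclass
class FoldArtifacts:
    """Per-fold fitted state, exposed for leakage auditing."""

    test_patients: tuple[str, ...]
    train_patients: tuple[str, ...]
    scaler_mean: np.ndarray
    n_train_after_balance: int
    selected_features: tuple[str, ...]


def run_cv(
    table: pd.DataFrame,
    scheme: CVScheme,
    spec: ClassifierSpec | EnsembleSpec,
    feature_subset: list[str] | None = None,
    seed: int = 0,
    selection_mode: str = "fixed",
    selection_min_votes: int = 4,
    selection_k: int = 25,
    balance: bool = True,
) -> tuple[EvaluationReport, list[FoldArtifacts]]:
    """Patient-grouped cross-validation over a ROI feature table.

    ``table`` must carry ``patient_id``, ``view``, ``label`` (0/1) columns
    plus feature columns. Per fold the scaler, ADASYN and — when
    ``selection_mode='per_fold'`` — the feature selection are fitted on
    training patients only; out-of-fold predictions are pooled into a single
    report.
    """
    from .selection import RANKERS, majority_merge, rank_features

    meta_cols = {"patient_id", "view", "roi_id", "label"}
    feature_cols = [c for c in table.columns if c not in meta_cols]
    if feature_subset is not None:
        missing = set(feature_subset) - set(feature_cols)
        if missing:
            raise ValueError(f"subset names missing from table: {sorted(missing)}")
    y_all = table["label"].to_numpy(dtype=int)
    pids = table["patient_id"].to_numpy(dtype=str)
    patient_labels = {
        p: int(table.loc[table["patient_id"] == p, "label"].max()) for p in set(pids)
    }
    folds = make_folds(pids, patient_labels, scheme, seed=seed)

    pred_rows = []
    artifacts: list[FoldArtifacts] = []
    for fold_id, (train_p, test_p) in enumerate(folds):
        tr = np.isin(pids, train_p)
        te = np.isin(pids, test_p)
        assert not np.intersect1d(pids[tr], pids[te]).size, "patient leakage"
        cols = list(feature_subset) if feature_subset is not None else feature_cols
        if selection_mode == "per_fold":
            lists = []
            for ranker in RANKERS:
                if ranker in ("sequential_forward", "sequential_backward"):
                    continue  # wrapper selectors are offline tools, too slow per fold
                lists.append(
                    rank_features(
                        table.loc[tr, feature_cols],
                        y_all[tr],
                        ranker,
                        k=min(selection_k, len(feature_cols)),
                        seed=seed,
                    )
                )
            cols = majority_merge(
                lists, min_votes=min(selection_min_votes, len(lists)),
                registry=feature_cols,
            ).names
        X_tr = table.loc[tr, cols].to_numpy(dtype=float)
        X_te = table.loc[te, cols].to_numpy(dtype=float)
        y_tr, y_te = y_all[tr], y_all[te]

        scaler = StandardScaler().fit(X_tr)
        X_tr_s = scaler.transform(X_tr)
        X_te_s = scaler.transform(X_te)
        if balance and len(np.unique(y_tr)) == 2:
            X_bal, y_bal = adasyn_balance(X_tr_s, y_tr, seed=seed + fold_id)
        else:
            X_bal, y_bal = X_tr_s, y_tr

        if isinstance(spec, EnsembleSpec):
            models = [train_classifier(m, X_bal, y_bal) for m in spec.members]
            scores, labels = ensemble_predict(spec, models, X_te_s)
        else:
            model = train_classifier(spec, X_bal, y_bal)
            try:
                scores = _positive_proba(model, X_te_s)
            except AttributeError:
                scores = model.predict(X_te_s).astype(float)
            labels = (scores >= 0.5).astype(int)

        sub = table.loc[te, ["patient_id", "view", "roi_id", "label"]].copy()
        sub["score"] = scores
        sub["pred"] = labels
        sub["fold"] = fold_id
        pred_rows.append(sub)
        artifacts.append(
            FoldArtifacts(
                test_patients=tuple(sorted(test_p)),
                train_patients=tuple(sorted(train_p)),
                scaler_mean=scaler.mean_.copy(),
                n_train_after_balance=len(y_bal),
                selected_features=tuple(cols),
            )
        )

    preds = pd.concat(pred_rows, ignore_index=True)
    report = compute_metrics(preds)
    return report, artifacts


def compute_metrics(preds: pd.DataFrame) -> EvaluationReport:
    """Pooled confusion counts, percentages, rank AUC and FP per image.

    A malignant patient counts as detected (per-patient sensitivity) if any
    of their true-positive ROIs in either view is flagged.
    """
    y = preds["label"].to_numpy(dtype=int)
    p = preds["pred"].to_numpy(dtype=int)
    if len(y) != len(p):
        raise ValueError("label/prediction length mismatch")
    tp = int(((y == 1) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    sens = percentage(tp, tp + fn)
    spec = percentage(tn, tn + fp)
    acc = percentage(tp + tn, len(y))
    scores = preds["score"].to_numpy(dtype=float)
    auc = float(roc_auc_score(y, scores)) if len(np.unique(y)) == 2 else float("nan")
    n_images = max(len(preds[["patient_id", "view"]].drop_duplicates()), 1)
    fp_per_image = fp / n_images

    mal = preds[preds["label"] == 1]
    mal_patients = mal["patient_id"].unique()
    if len(mal_patients):
        det = mal[mal["pred"] == 1]["patient_id"].unique()
        pps = len(det) / len(mal_patients)
    else:
        pps = float("nan")
    return EvaluationReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec, accuracy=acc,
        auc=auc, fp_per_image=fp_per_image,
        per_patient_sensitivity=pps,
        fold_predictions=preds,
    )


def percentage(numerator: int, denominator: int) -> float:
    """Counts to percent, e.g. (58, 62) -> 93.55 (to be printed at 2 dp)."""
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


# ---------------------------------------------------------------------------
# paired comparison


def mcnemar_test(
    preds_a: np.ndarray, preds_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Continuity-corrected McNemar chi-square on the correct/incorrect
    discordant pairs of two classifiers evaluated on the same ROIs."""
    a_ok = np.asarray(preds_a) == np.asarray(labels)
    b_ok = np.asarray(preds_b) == np.asarray(labels)
    b_count = int((a_ok & ~b_ok).sum())
    c_count = int((~a_ok & b_ok).sum())
    if b_count + c_count == 0:
        return 0.0, 1.0
    table = [[int((a_ok & b_ok).sum()), b_count], [c_count, int((~a_ok & ~b_ok).sum())]]
    res = _sm_mcnemar(table, exact=False, correction=True)
    return float(res.statistic), float(res.pvalue)


def mcnemar_extended(
    predictions: dict[str, np.ndarray], labels: np.ndarray, reference: str
) -> pd.DataFrame:
    """Pairwise McNemar tests of one reference classifier against all others,
    with Bonferroni adjustment over the comparisons (the multi-classifier
    'extended' form)."""
    others = [k for k in predictions if k != reference]
    rows = []
    m = len(others)
    for name in others:
        stat, p = mcnemar_test(predictions[reference], predictions[name], labels)
        rows.append(
            {"classifier": name, "statistic": stat, "p_value": p,
             "p_adjusted": min(1.0, p * m)}
        )
    return pd.DataFrame(rows)
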