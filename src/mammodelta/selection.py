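"""Feature ranking by eight techniques and majority-rule merging.

Each ranker returns an ordered top-k list of feature names; the final subset
keeps every feature appearing in at least ``min_votes`` of the lists. On the
published eight rankings (shipped as package data) a threshold of 4 of 8
votes reproduces the 14-feature reference selection, so 4 is the default.

Rankers:

* ``t_test`` — Welch two-sample t statistic magnitude per feature;
* ``mrmr`` — greedy maximum-relevance-minimum-redundancy (MID scheme) on
  mutual information estimates;
* ``importance_extra_trees`` / ``importance_random_forest`` — impurity
  importances from randomized-tree ensembles;
* ``importance_xgboost`` — gain importances from gradient-boosted trees;
* ``univariate_k_best`` — ANOVA-F univariate score ranking (SelectKBest);
* ``sequential_forward`` / ``sequential_backward`` — greedy wrapper
  selection around a linear-discriminant base learner with internal 5-fold
  cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.feature_selection import (
    SelectKBest,
    SequentialFeatureSelector,
    f_classif,
    mutual_info_classif,
)

RANKERS = (
    "t_test",
    "mrmr",
    "importance_extra_trees",
    "importance_random_forest",
    "importance_xgboost",
    "univariate_k_best",
    "sequential_forward",
    "sequential_backward",
)

#: ranker keys used in the shipped reference-table fixture
_TABLE_KEYS = {
    "t_test": "t_test",
    "mrmr": "mrmr",
    "importance_extra_trees": "fi_et",
    "importance_random_forest": "fi_rf",
    "importance_xgboost": "fi_xgb",
    "univariate_k_best": "select_k_best",
    "sequential_forward": "sfs",
    "sequential_backward": "sbs",
}

DEFAULT_MIN_VOTES = 4
DEFAULT_LIST_LENGTH = 25


@dataclass
class RankedFeatureList:
    ranker: str
    selected: list[str]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("duplicate names in ranked list")


@dataclass
class FeatureSubset:
    names: list[str]  # registry order
    rule: str

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("empty feature subset")


def load_reference_rankings() -> dict[str, RankedFeatureList]:
    """The eight published ranked lists, shipped as package data."""
    text = resources.files("mammodelta.data").joinpath("reference_rankings.json").read_text()
    raw = json.loads(text)
    return {
        ranker: RankedFeatureList(ranker=ranker, selected=raw[key])
        for ranker, key in _TABLE_KEYS.items()
    }


def _welch_t_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    g0, g1 = X[y == 0], X[y == 1]
    t, _ = stats.ttest_ind(g0, g1, equal_var=False, axis=0)
    return np.nan_to_num(np.abs(t), nan=0.0)


def _mrmr_order(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> list[int]:
    """Greedy MID mRMR: maximize MI(f; y) - mean MI(f; selected)."""
    n_features = X.shape[1]
    relevance = mutual_info_classif(X, y, random_state=seed)
    # pairwise feature MI on a discretized copy (equal-width 16 bins)
    Xq = np.empty_like(X, dtype=np.int64)
    for j in range(n_features):
        col = X[:, j]
        rng_ = np.ptp(col)
        Xq[:, j] = np.clip(
            ((col - col.min()) / (rng_ + 1e-12) * 16).astype(np.int64), 0, 15
        )

    def pair_mi(a: np.ndarray, b: np.ndarray) -> float:
        joint = np.zeros((16, 16))
        np.add.at(joint, (a, b), 1.0)
        joint /= joint.sum()
        pa, pb = joint.sum(1, keepdims=True), joint.sum(0, keepdims=True)
        nz = joint > 0
        return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())

    selected: list[int] = [int(np.argmax(relevance))]
    cached: dict[tuple[int, int], float] = {}
    while len(selected) < min(k, n_features):
        best_j, best_score = -1, -np.inf
        for j in range(n_features):
            if j in selected:
                continue
            red = 0.0
            for s in selected:
                key = (min(j, s), max(j, s))
                if key not in cached:
                    cached[key] = pair_mi(Xq[:, j], Xq[:, s])
                red += cached[key]
            score = relevance[j] - red / len(selected)
            if score > best_score:
                best_score, best_j = score, j
        selected.append(best_j)
    return selected


def rank_features(
    X: pd.DataFrame,
    y: np.ndarray,
    ranker: str,
    k: int = DEFAULT_LIST_LENGTH,
    seed: int = 0,
) -> RankedFeatureList:
    """Top-k feature names per the named technique (see module docstring)."""
    if ranker not in RANKERS:
        raise ValueError(f"unknown ranker {ranker!r}; choose from {RANKERS}")
    names = list(X.columns)
    if k > len(names):
        raise ValueError(f"k={k} exceeds registry size {len(names)}")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes to rank features")
    Xv = X.to_numpy(dtype=float)
    # zero-variance features carry no class information and break the
    # LDA-based wrappers; exclude them up front
    keep = np.flatnonzero(Xv.std(axis=0) > 0)
    if keep.size == 0:
        raise ValueError("all features have zero variance")
    if keep.size < len(names):
        X = X.iloc[:, keep]
        names = list(X.columns)
        Xv = Xv[:, keep]
        k = min(k, len(names))
    scores: np.ndarray | None = None

    if ranker == "t_test":
        scores = _welch_t_scores(Xv, y)
    elif ranker == "univariate_k_best":
        sel = SelectKBest(score_func=f_classif, k=k).fit(Xv, y)
        scores = np.nan_to_num(sel.scores_, nan=0.0)
    elif ranker == "importance_extra_trees":
        est = ExtraTreesClassifier(n_estimators=200, random_state=seed, n_jobs=1)
        scores = est.fit(Xv, y).feature_importances_
    elif ranker == "importance_random_forest":
        est = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
        scores = est.fit(Xv, y).feature_importances_
    elif ranker == "importance_xgboost":
        from xgboost import XGBClassifier

        est = XGBClassifier(
            n_estimators=100, max_depth=4, random_state=seed,
            n_jobs=1, verbosity=0, eval_metric="logloss",
        )
        scores = est.fit(Xv, y).feature_importances_
    elif ranker == "mrmr":
        order = _mrmr_order(Xv, y, k, seed)
        return RankedFeatureList(ranker=ranker, selected=[names[j] for j in order[:k]])
    else:  # wrapper selectors
        direction = "forward" if ranker == "sequential_forward" else "backward"
        sfs = SequentialFeatureSelector(
            LinearDiscriminantAnalysis(),
            n_features_to_select=k,
            direction=direction,
            cv=5,
            n_jobs=1,
        )
        sfs.fit(Xv, y)
        chosen = [names[j] for j in np.flatnonzero(sfs.get_support())]
        return RankedFeatureList(ranker=ranker, selected=chosen)

    order = np.argsort(-scores, kind="stable")[:k]
    return RankedFeatureList(
        ranker=ranker,
        selected=[names[j] for j in order],
        scores=[float(scores[j]) for j in order],
    )


def majority_merge(
    lists: list[RankedFeatureList] | dict[str, RankedFeatureList],
    min_votes: int = DEFAULT_MIN_VOTES,
    registry: list[str] | None = None,
) -> FeatureSubset:
    """Keep features appearing in >= min_votes of the ranked lists.

    Output order follows the registry when given, otherwise first-appearance
    order across the lists (deterministic, permutation-invariant because
    appearance order is resolved by vote then name).
    """
    if isinstance(lists, dict):
        lists = list(lists.values())
    if len(lists) < 2:
        raise ValueError("need at least two ranked lists to merge")
    votes: dict[str, int] = {}
    for rl in lists:
        for name in rl.selected:
            votes[name] = votes.get(name, 0) + 1
    chosen = {n for n, v in votes.items() if v >= min_votes}
    if not chosen:
        raise ValueError(
            f"majority merge at min_votes={min_votes} is empty; lower min_votes"
        )
    if registry is not None:
        ordered = [n for n in registry if n in chosen]
        missing = chosen - set(ordered)
        if missing:
            raise ValueError(f"selected names outside registry: {sorted(missing)}")
    else:
        ordered = sorted(chosen, key=lambda n: (-votes[n], n))
    return FeatureSubset(names=ordered, rule=f">= {min_votes} of {len(lists)} rankers")


def reference_subset() -> FeatureSubset:
    """Majority merge of the shipped reference rankings (the 14 features)."""
    return majority_merge(load_reference_rankings(), DEFAULT_MIN_VOTES)
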