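"""ADASYN balancing, classifier training, voting, grouped CV, metrics and
the paired McNemar comparison."""

import numpy as np
import pandas as pd
import pytest

from mammodelta.classify_eval import (
    ClassifierSpec,
    CVScheme,
    EnsembleSpec,
    adasyn_balance,
    compute_metrics,
    default_ensemble_spec,
    ensemble_predict,
    make_folds,
    mcnemar_extended,
    mcnemar_test,
    percentage,
    run_cv,
    train_classifier,
)


def _imbalanced(n_min=10, n_maj=100, d=4, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(3.0, 1.0, (n_min, d)), rng.normal(0.0, 1.0, (n_maj, d))]
    )
    y = np.array([1] * n_min + [0] * n_maj)
    return X, y


class TestAdasyn:
    def test_balanced_input_nearly_unchanged(self):
        X, y = _imbalanced(50, 50)
        Xb, yb = adasyn_balance(X, y, seed=0)
        assert len(yb) <= len(y) * 1.01

    def test_minority_count_balanced(self):
        X, y = _imbalanced(10, 100)
        Xb, yb = adasyn_balance(X, y, seed=0)
        n_min = (yb == 1).sum()
        assert 90 <= n_min <= 110
        # originals retained unchanged, in order
        np.testing.assert_array_equal(Xb[: len(X)], X)

    def test_synthetic_points_on_minority_segments(self):
        X, y = _imbalanced(20, 100)
        Xb, yb = adasyn_balance(X, y, seed=1)
        X_min = X[y == 1]
        new = Xb[len(X):]
        assert len(new) > 0
        for p in new[:50]:
            # p = a + lam*(b - a) for some minority pair (a, b):
            # check the best pair leaves negligible residual
            best = np.inf
            for i in range(len(X_min)):
                d_i = p - X_min[i]
                for j in range(len(X_min)):
                    seg = X_min[j] - X_min[i]
                    denom = seg @ seg
                    if denom == 0:
                        continue
                    lam = np.clip((d_i @ seg) / denom, 0, 1)
                    best = min(best, float(np.linalg.norm(d_i - lam * seg)))
            assert best < 1e-9

    def test_tiny_minority_falls_back_with_warning(self):
        X, y = _imbalanced(3, 50)
        with pytest.warns(UserWarning, match="duplication"):
            Xb, yb = adasyn_balance(X, y, seed=0)
        assert (yb == 1).sum() >= 45

    def test_deterministic(self):
        X, y = _imbalanced(10, 80)
        a = adasyn_balance(X, y, seed=5)[0]
        b = adasyn_balance(X, y, seed=5)[0]
        np.testing.assert_array_equal(a, b)


class TestClassifiers:
    @pytest.mark.parametrize("family", ["lda", "svm"])
    def test_separable_data_fit_perfectly(self, family):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (40, 2)), rng.normal(3, 0.3, (40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        spec = ClassifierSpec(family, {"kernel": "linear"} if family == "svm" else {})
        model = train_classifier(spec, X, y)
        assert (model.predict(X) == y).all()

    @pytest.mark.parametrize("family", ["random_forest", "extra_trees", "ann", "mlp"])
    def test_stochastic_families_deterministic_under_seed(self, family):
        X, y = _imbalanced(30, 30)
        spec = ClassifierSpec(family, seed=42)
        p1 = train_classifier(spec, X, y).predict(X)
        p2 = train_classifier(spec, X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_fold_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="single-class"):
            train_classifier(ClassifierSpec("lda"), X, np.zeros(10))

    def test_knn_k_constrained(self):
        with pytest.raises(ValueError):
            ClassifierSpec("knn", {"k": 4})

    def test_svm_kernel_constrained(self):
        with pytest.raises(ValueError):
            ClassifierSpec("svm", {"kernel": "sigmoid"})
        spec = ClassifierSpec("svm", {"kernel": "polynomial"})
        assert spec.hyperparams["kernel"] == "poly"

    def test_label_permutation_gives_chance_auc(self):
        """Held-out AUC on label-permuted training data stays near 0.5."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        aucs = []
        for rep in range(20):
            X = rng.standard_normal((120, 5))
            y = rng.permutation(np.repeat([0, 1], 60))
            model = train_classifier(ClassifierSpec("lda"), X[:80], y[:80])
            s = model.predict_proba(X[80:])[:, 1]
            aucs.append(roc_auc_score(y[80:], s))
        assert 0.4 < float(np.mean(aucs)) < 0.6


class TestEnsemble:
    class _Fixed:
        def __init__(self, proba, label):
            self._p, self._l = proba, label
            self.classes_ = np.array([0, 1])

        def predict_proba(self, X):
            return np.tile([1 - self._p, self._p], (len(X), 1))

        def predict(self, X):
            return np.full(len(X), self._l)

    def test_soft_mean_threshold(self):
        spec = EnsembleSpec(
            members=[ClassifierSpec("lda")] * 3, voting="soft"
        )
        models = [self._Fixed(p, int(p >= 0.5)) for p in (0.9, 0.2, 0.7)]
        scores, labels = ensemble_predict(spec, models, np.zeros((4, 2)))
        assert scores[0] == pytest.approx(0.6)
        assert labels.tolist() == [1, 1, 1, 1]

    def test_hard_majority_and_tie_positive(self):
        spec = EnsembleSpec(members=[ClassifierSpec("lda")] * 4, voting="hard")
        models = [self._Fixed(0.5, l) for l in (1, 1, 0, 0)]  # 2-2 tie
        _, labels = ensemble_predict(spec, models, np.zeros((3, 2)))
        assert labels.tolist() == [1, 1, 1]

    def test_all_agree(self):
        spec = EnsembleSpec(members=[ClassifierSpec("lda")] * 3, voting="hard")
        models = [self._Fixed(0.9, 1)] * 3
        _, labels = ensemble_predict(spec, models, np.zeros((2, 2)))
        assert labels.tolist() == [1, 1]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            EnsembleSpec(members=[ClassifierSpec("lda")], voting="soft")
        with pytest.raises(ValueError):
            EnsembleSpec(members=[ClassifierSpec("lda")] * 2, voting="ranked")


def _toy_table(n_patients=8, rois_per_view=6, seed=0):
    """Separable ROI table: positives shifted in both features."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"p{i}"
        malignant = i < n_patients // 2
        for view in ("CC", "MLO"):
            for j in range(rois_per_view):
                pos = malignant and j == 0
                rows.append(
                    {
                        "patient_id": pid,
                        "view": view,
                        "roi_id": j,
                        "label": int(pos),
                        "f1": (3.0 if pos else 0.0) + 0.3 * rng.standard_normal(),
                        "f2": (2.0 if pos else 0.0) + 0.3 * rng.standard_normal(),
                        "f3": rng.standard_normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestCV:
    def test_lopo_fold_structure(self):
        table = _toy_table()
        scheme = CVScheme(kind="lopo")
        labels = {f"p{i}": int(i < 4) for i in range(8)}
        folds = make_folds(table["patient_id"].to_numpy(), labels, scheme)
        assert len(folds) == 8
        for train_p, test_p in folds:
            assert len(test_p) == 1
            assert set(test_p).isdisjoint(train_p)
            assert len(train_p) == 7

    def test_kfold_stratified_disjoint(self):
        table = _toy_table(n_patients=10)
        labels = {f"p{i}": int(i < 5) for i in range(10)}
        folds = make_folds(table["patient_id"].to_numpy(), labels, CVScheme("kfold", 5))
        seen = []
        for train_p, test_p in folds:
            assert set(test_p).isdisjoint(train_p)
            # stratification: one malignant + one normal patient per test fold
            assert sum(labels[p] for p in test_p) == 1
            seen += list(test_p)
        assert sorted(seen) == sorted(labels)

    def test_perfect_separation_recovered(self):
        table = _toy_table()
        report, folds = run_cv(
            table, CVScheme("lopo"), ClassifierSpec("lda"),
            feature_subset=["f1", "f2"], seed=0,
        )
        assert report.sensitivity == 100.0
        assert report.auc == 1.0
        assert len(folds) == 8

    def test_fold_artifacts_expose_training_state(self):
        table = _toy_table()
        _, folds = run_cv(
            table, CVScheme("lopo"), ClassifierSpec("lda"),
            feature_subset=["f1", "f2"], seed=0,
        )
        for art in folds:
            tr = table[table["patient_id"].isin(art.train_patients)]
            np.testing.assert_allclose(
                art.scaler_mean, tr[["f1", "f2"]].mean().to_numpy()
            )


class TestMetrics:
    # every printed row of the reference comparison: (tp, tp+fn, tn, tn+fp,
    # sensitivity%, specificity%, accuracy%)
    TABLE_ROWS = [
        ("random_forest", 50, 62, 7247, 7263, 80.65, 99.78, 99.62),
        ("gradient_boosting", 51, 62, 7227, 7263, 82.26, 99.50, 99.36),
        ("mlp", 53, 62, 7177, 7263, 85.48, 98.82, 98.70),
        ("knn", 56, 62, 7174, 7263, 90.32, 98.77, 98.70),
        ("adaboost", 56, 62, 7233, 7263, 90.32, 99.59, 99.51),
        ("svm", 57, 62, 6813, 7263, 91.94, 93.80, 93.79),
        ("naive_bayes", 57, 62, 7052, 7263, 91.94, 97.09, 97.05),
        ("ann", 57, 62, 7221, 7263, 91.94, 99.42, 99.36),
        ("lda", 58, 62, 6973, 7263, 93.55, 96.01, 95.99),
        ("ensemble_voting", 58, 62, 7179, 7263, 93.55, 98.84, 98.80),
    ]

    @pytest.mark.parametrize("row", TABLE_ROWS, ids=[r[0] for r in TABLE_ROWS])
    def test_printed_percentages_reproduced(self, row):
        _, tp, pos, tn, neg, sens, spec, acc = row
        assert round(percentage(tp, pos), 2) == sens
        assert round(percentage(tn, neg), 2) == spec
        assert round(percentage(tp + tn, pos + neg), 2) == acc

    def test_counts_sum_and_rates(self):
        preds = pd.DataFrame(
            {
                "patient_id": ["a"] * 4 + ["b"] * 4,
                "view": ["CC"] * 4 + ["MLO"] * 4,
                "roi_id": range(8),
                "label": [1, 1, 0, 0, 1, 0, 0, 0],
                "pred": [1, 0, 0, 1, 1, 0, 0, 0],
                "score": [0.9, 0.4, 0.2, 0.6, 0.8, 0.1, 0.2, 0.3],
            }
        )
        r = compute_metrics(preds)
        assert (r.tp, r.fn, r.tn, r.fp) == (2, 1, 4, 1)
        assert r.tp + r.fn + r.tn + r.fp == len(preds)
        assert r.fp_per_image == pytest.approx(1 / 2)
        assert r.per_patient_sensitivity == 1.0

    def test_perfect_scores_auc_one(self):
        preds = pd.DataFrame(
            {
                "patient_id": ["a"] * 6,
                "view": ["CC"] * 6,
                "roi_id": range(6),
                "label": [1, 1, 0, 0, 0, 0],
                "pred": [1, 1, 0, 0, 0, 0],
                "score": [0.9, 0.8, 0.3, 0.2, 0.1, 0.05],
            }
        )
        assert compute_metrics(preds).auc == 1.0

    def test_random_scores_auc_near_half(self, rng):
        n = 5000
        preds = pd.DataFrame(
            {
                "patient_id": ["a"] * n,
                "view": ["CC"] * n,
                "roi_id": range(n),
                "label": rng.integers(0, 2, n),
                "pred": rng.integers(0, 2, n),
                "score": rng.random(n),
            }
        )
        assert abs(compute_metrics(preds).auc - 0.5) < 0.05


class TestMcNemar:
    def test_identical_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        p = np.array([0, 1, 1, 1, 0])
        stat, pval = mcnemar_test(p, p, y)
        assert pval == 1.0

    def test_continuity_corrected_statistic(self):
        """Discordant counts b=10, c=2 -> (|10-2|-1)^2/12 = 49/12."""
        y = np.zeros(40, dtype=int)
        a = np.zeros(40, dtype=int)
        b = np.zeros(40, dtype=int)
        # a correct & b wrong on 10; a wrong & b correct on 2
        b[:10] = 1
        a[10:12] = 1
        stat, pval = mcnemar_test(a, b, y)
        assert stat == pytest.approx(49 / 12)

    def test_symmetric_discordance_max_p(self):
        """With b = c the test sees no asymmetry: p is (near) maximal and
        larger than for any asymmetric split of the same discordant total."""
        def p_for(nb, nc):
            y = np.zeros(40, dtype=int)
            a = np.zeros(40, dtype=int)
            b = np.zeros(40, dtype=int)
            a[:nb] = 1           # a wrong, b correct on nb
            b[nb:nb + nc] = 1    # b wrong, a correct on nc
            return mcnemar_test(a, b, y)[1]

        p_sym = p_for(5, 5)
        assert p_sym > 0.7
        assert p_sym > p_for(8, 2)
        assert p_sym > p_for(9, 1)

    def test_extended_pairwise_adjustment(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        preds = {
            "ref": y.copy(),
            "noisy": np.where(rng.random(200) < 0.2, 1 - y, y),
            "bad": 1 - y,
        }
        df = mcnemar_extended(preds, y, reference="ref")
        assert set(df["classifier"]) == {"noisy", "bad"}
        assert (df["p_adjusted"] >= df["p_value"]).all()
        assert df.loc[df["classifier"] == "bad", "p_value"].iloc[0] < 0.001


def test_default_ensemble_composition():
    spec = default_ensemble_spec()
    families = [m.family for m in spec.members]
    assert families == ["lda", "knn", "svm", "naive_bayes", "extra_trees"]
    assert spec.voting == "soft"
    knn = spec.members[1]
    assert knn.hyperparams["k"] == 9
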