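"""Confusion-matrix metric formulas, classifier families, CV and ROC."""

import numpy as np
import pytest

from vocalmarkers.classify import (
    ClassifierSpec,
    ConfusionMatrix,
    compute_metrics,
    cross_validate,
    feature_matrix,
    fit_classifier,
    roc_auc_cv,
    roc_points,
)
from vocalmarkers.dataset import stratified_split
from vocalmarkers.errors import (
    DegenerateTrainingError,
    ParameterError,
    StratificationError,
)

FAMILIES = ("svm", "gboost", "dtree", "rforest", "knn")


def _metrics_oracle(tp, tn, fp, fn):
    """Direct transcription of the six binary metric formulas."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return acc, sens, spec, prec, f1, mcc


class TestComputeMetrics:
    def test_study_svm_confusion_matrix_reproduces_table_row(self):
        cm = ConfusionMatrix.from_binary_counts(tp=194, tn=113, fp=7, fn=3)
        rounded = compute_metrics(cm).rounded(2)
        assert rounded["acc"] == 0.97
        assert rounded["prec"] == 0.97
        assert rounded["mcc"] == 0.93

    def test_study_xgboost_confusion_matrix_mcc(self):
        cm = ConfusionMatrix.from_binary_counts(tp=195, tn=114, fp=6, fn=2)
        assert compute_metrics(cm).rounded(2)["mcc"] == 0.95

    def test_perfect_and_inverted_prediction(self):
        perfect = compute_metrics(ConfusionMatrix.from_binary_counts(50, 50, 0, 0))
        assert (perfect.acc, perfect.sens, perfect.spec, perfect.prec,
                perfect.f1, perfect.mcc) == (1, 1, 1, 1, 1, 1)
        inverted = compute_metrics(ConfusionMatrix.from_binary_counts(0, 0, 50, 50))
        assert inverted.mcc == -1

    def test_identities_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 200, 4))
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionMatrix.from_binary_counts(tp, tn, fp, fn))
            acc, sens, spec, prec, f1, mcc = _metrics_oracle(tp, tn, fp, fn)
            assert m.acc == pytest.approx(acc, abs=1e-12)
            assert m.sens == pytest.approx(sens, abs=1e-12)
            assert m.spec == pytest.approx(spec, abs=1e-12)
            assert m.prec == pytest.approx(prec, abs=1e-12)
            assert m.f1 == pytest.approx(f1, abs=1e-12)
            if m.mcc_defined:
                assert m.mcc == pytest.approx(mcc, abs=1e-12)
                assert abs(m.mcc) <= 1 + 1e-12
                # swap symmetry of the correlation
                swapped = compute_metrics(
                    ConfusionMatrix.from_binary_counts(tn, tp, fn, fp)
                )
                assert swapped.mcc == pytest.approx(m.mcc, abs=1e-12)
            if prec + sens > 0:
                assert m.f1 == pytest.approx(
                    2 / (1 / max(prec, 1e-300) + 1 / max(sens, 1e-300)), abs=1e-9
                )

    def test_mcc_zero_for_margin_proportional_matrix(self):
        # counts proportional to the product of their margins => no correlation
        m = compute_metrics(ConfusionMatrix.from_binary_counts(tp=20, tn=30, fp=20, fn=30))
        assert m.mcc == pytest.approx(0.0, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionMatrix(matrix=np.zeros((2, 2)), labels=(0, 1))

    def test_multiclass_macro_average(self):
        m3 = ConfusionMatrix(
            matrix=np.array([[10, 0, 0], [0, 9, 1], [0, 2, 8]]), labels=(0, 1, 2)
        )
        metrics = compute_metrics(m3)
        assert metrics.acc == pytest.approx(27 / 30)
        per_class = [
            _metrics_oracle(*m3.binary_counts(positive=c))[1] for c in (0, 1, 2)
        ]
        assert metrics.sens == pytest.approx(np.mean(per_class))


class TestClassifierFamilies:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separated_table_reaches_95_percent_holdout(self, family, separated_table):
        """Class means 3 sd apart on 5 features make the Bayes error tiny;
        every family must clear 95% on an independent draw of the same
        distribution (large enough that estimator variance is negligible)."""
        from vocalmarkers.synth import separated_feature_table

        holdout = separated_feature_table({0: 500, 1: 500}, separation_sd=3.0, seed=99)
        model = fit_classifier(ClassifierSpec(family=family), separated_table, seed=0)
        X_test, y_test, _ = feature_matrix(holdout)
        acc = np.mean(model.predict(X_test) == y_test)
        assert acc >= 0.95

    def test_single_class_training_rejected(self, separated_table):
        ill = separated_table[separated_table["class_label"] == 1]
        with pytest.raises(DegenerateTrainingError):
            fit_classifier(ClassifierSpec(family="svm"), ill)

    def test_missing_values_direct_to_preprocess(self, separated_table):
        broken = separated_table.copy()
        broken.iloc[0, broken.columns.get_loc("F0")] = np.nan
        with pytest.raises(ParameterError, match="preprocess"):
            fit_classifier(ClassifierSpec(family="svm"), broken)

    def test_deterministic_predictions(self, separated_table):
        train, test = stratified_split(separated_table, 0.3, seed=1)
        X_test, _, _ = feature_matrix(test)
        a = fit_classifier(ClassifierSpec(family="rforest"), train, seed=3).predict(X_test)
        b = fit_classifier(ClassifierSpec(family="rforest"), train, seed=3).predict(X_test)
        assert np.array_equal(a, b)

    def test_unknown_family_rejected(self):
        with pytest.raises(ParameterError):
            ClassifierSpec(family="mlp")


class TestCrossValidate:
    def test_pooled_counts_cover_every_row(self, separated_table):
        pooled, folds, cm = cross_validate(
            ClassifierSpec(family="dtree"), separated_table, k=10, seed=0
        )
        assert cm.total == len(separated_table)
        assert len(folds) == 10

    def test_separable_data_is_perfectly_classified(self, separated_table):
        pooled, _, _ = cross_validate(
            ClassifierSpec(family="svm"), separated_table, k=5, seed=0
        )
        assert pooled.acc >= 0.99

    def test_k_of_one_rejected(self, separated_table):
        with pytest.raises(ParameterError):
            cross_validate(ClassifierSpec(family="svm"), separated_table, k=1)

    def test_class_smaller_than_k_rejected(self, separated_table):
        small = separated_table.groupby("class_label").head(5)
        with pytest.raises(StratificationError):
            cross_validate(ClassifierSpec(family="svm"), small, k=10)


class TestROC:
    def test_scores_equal_to_labels_give_unit_auc(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        _, _, auc = roc_points(y, y.astype(float))
        assert auc == 1.0

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(23)
        y = rng.integers(0, 2, 2000)
        scores = rng.normal(size=2000)
        _, _, auc = roc_points(y, scores)
        assert abs(auc - 0.5) < 0.05

    def test_constant_scores_give_half_by_tie_convention(self):
        y = np.array([0, 1] * 20)
        _, _, auc = roc_points(y, np.zeros(40))
        assert auc == pytest.approx(0.5)

    def test_cv_auc_high_on_separable_table(self, separated_table):
        out = roc_auc_cv(ClassifierSpec(family="gboost"), separated_table, k=3, seed=0)
        assert out["mean_auc"] > 0.99
        assert len(out["folds"]) == 3
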