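import math

import numpy as np
import pandas as pd
import pytest

from dilic.classifier_eval import (
    MetricsReport,
    ModelFamily,
    ModelSpec,
    Prediction,
    confusion_metrics,
    cross_validate,
    metrics_from_counts,
    predict,
    train,
)
from dilic.corpus_io import Label
from dilic.pattern_scoring import FeatureMatrix, RESERVED_COLUMNS, WeightConfig


def _matrix(X, y, prefix="f"):
    n, p = X.shape
    cols = [f"{prefix}{j}" for j in range(p)] + list(RESERVED_COLUMNS)
    full = np.hstack([X, np.zeros((n, 2)), X.sum(axis=1, keepdims=True)])
    idx = pd.Index([f"d{i}" for i in range(n)], name="doc_id")
    values = pd.DataFrame(full, index=idx, columns=cols)
    labels = pd.Series(
        [Label.POSITIVE if v else Label.NEGATIVE for v in y], index=idx, name="label"
    )
    return FeatureMatrix(values=values, labels=labels, config=WeightConfig())


def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    X = rng.normal(size=(n, 3)) + y[:, None] * 8.0
    return _matrix(X, y)


class TestCrossValidate:
    def test_separable_matrix_reaches_perfect_accuracy(self):
        m = _separable()
        results, best = cross_validate(m, [ModelSpec(family=ModelFamily.LOGISTIC, seed=1)])
        assert max(r.mean_accuracy for r in results) == 1.0
        assert best.family is ModelFamily.LOGISTIC

    def test_tied_accuracy_resolved_by_family_order(self):
        m = _separable()
        specs = [
            ModelSpec(family=ModelFamily.RANDOM_FOREST, seed=1),
            ModelSpec(family=ModelFamily.LOGISTIC, seed=1),
        ]
        results, best = cross_validate(m, specs)
        accs = {r.spec.family: r.mean_accuracy for r in results}
        assert accs[ModelFamily.LOGISTIC] == accs[ModelFamily.RANDOM_FOREST] == 1.0
        assert best.family is ModelFamily.LOGISTIC  # earlier in the enum

    def test_reports_per_fold_accuracies(self):
        m = _separable()
        results, _ = cross_validate(m, [ModelSpec(family=ModelFamily.LOGISTIC, cv_folds=4)])
        assert len(results[0].fold_accuracies) == 4


class TestPredict:
    @pytest.fixture()
    def fitted(self):
        m = _separable()
        return train(m, ModelSpec(family=ModelFamily.LOGISTIC, seed=0)), m

    def test_degenerate_cutoffs(self, fitted):
        model, m = fitted
        assert all(p.label is Label.POSITIVE for p in predict(model, m, cutoff=0.0))
        assert all(p.label is Label.NEGATIVE for p in predict(model, m, cutoff=1.0))

    def test_raising_cutoff_shrinks_positive_set(self, fitted):
        model, m = fitted
        counts = [
            sum(p.label is Label.POSITIVE for p in predict(model, m, cutoff=c))
            for c in (0.0, 0.3, 0.5, 0.7, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_manifest_mismatch_is_hard_error(self, fitted):
        model, m = fitted
        bad = FeatureMatrix(
            values=m.values.rename(columns={"f0": "g0"}),
            labels=m.labels,
            config=m.config,
        )
        with pytest.raises(ValueError, match="manifest"):
            predict(model, bad)

    def test_zero_variance_columns_dropped_at_training(self):
        m = _separable()
        m.values["f1"] = 0.0
        model = train(m, ModelSpec(family=ModelFamily.LOGISTIC))
        assert "f1" not in model.kept_columns
        assert model.input_manifest == m.manifest
        # prediction still works on a matrix with the full manifest
        assert len(predict(model, m)) == len(m.doc_ids)


class TestMetrics:
    def test_all_correct(self):
        r = metrics_from_counts(tp=5, fp=0, fn=0, tn=5)
        assert r.accuracy == r.precision == r.recall == r.f1 == 1.0

    def test_zero_predicted_positives(self, caplog):
        with caplog.at_level("WARNING"):
            r = metrics_from_counts(tp=0, fp=0, fn=3, tn=7)
        assert math.isnan(r.precision)
        assert r.recall == 0.0
        assert math.isnan(r.f1)
        assert "undefined" in caplog.text

    def test_counts_partition_the_documents(self):
        rng = np.random.default_rng(2)
        preds = [
            Prediction(f"d{i}", p, Label.POSITIVE if p > 0.5 else Label.NEGATIVE, 0.5)
            for i, p in enumerate(rng.uniform(size=40))
        ]
        truth = {
            f"d{i}": Label.POSITIVE if rng.random() < 0.5 else Label.NEGATIVE
            for i in range(40)
        }
        r = confusion_metrics(preds, truth)
        assert r.total == 40

    def test_permutation_invariant(self):
        preds = [
            Prediction("a", 0.9, Label.POSITIVE, 0.5),
            Prediction("b", 0.2, Label.NEGATIVE, 0.5),
            Prediction("c", 0.7, Label.POSITIVE, 0.5),
        ]
        truth = {"a": Label.POSITIVE, "b": Label.POSITIVE, "c": Label.NEGATIVE}
        assert confusion_metrics(preds, truth) == confusion_metrics(preds[::-1], truth)

    def test_doc_id_mismatch_rejected(self):
        preds = [Prediction("a", 0.9, Label.POSITIVE, 0.5)]
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics(preds, {"b": Label.POSITIVE})
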