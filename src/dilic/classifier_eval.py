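"""Classifier training, cross-validated model selection, thresholded
prediction, and confusion-matrix metrics.

Six interchangeable scikit-learn back ends are exposed through one enum;
the model with the highest mean stratified-CV accuracy wins (ties broken
by the fixed enum order).  A document is labelled positive when its
predicted positive-class probability strictly exceeds the cutoff
(default 0.5), so raising the cutoff can only shrink the positive set.
Zero-variance columns are dropped at training time and the surviving
column manifest travels with the model; prediction refuses a matrix
whose columns do not match the manifest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline as SkPipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .corpus_io import Label
from .pattern_scoring import FeatureMatrix, RESERVED_COLUMNS

logger = logging.getLogger(__name__)


class ModelFamily(Enum):
    LOGISTIC = "logistic"
    ELASTIC_NET = "elastic_net"
    RANDOM_FOREST = "random_forest"
    GBM = "gbm"
    SVM = "svm"
    NEURAL_NET = "neural_net"


@dataclass(frozen=True)
class ModelSpec:
    family: ModelFamily = ModelFamily.GBM
    hyperparameters: tuple = ()  # (name, value) pairs; tuple keeps the spec hashable
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


_SCALED = {ModelFamily.LOGISTIC, ModelFamily.ELASTIC_NET, ModelFamily.SVM, ModelFamily.NEURAL_NET}


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a spec (probability-capable)."""
    p = spec.params
    fam = spec.family
    if fam is ModelFamily.LOGISTIC:
        est = LogisticRegression(max_iter=p.get("max_iter", 2000), C=p.get("C", 1.0))
    elif fam is ModelFamily.ELASTIC_NET:
        est = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=p.get("l1_ratio", 0.5),
            C=p.get("C", 1.0), max_iter=p.get("max_iter", 3000),
        )
    elif fam is ModelFamily.RANDOM_FOREST:
        est = RandomForestClassifier(
            n_estimators=p.get("n_estimators", 200), max_depth=p.get("max_depth"),
            random_state=spec.seed, n_jobs=1,
        )
    elif fam is ModelFamily.GBM:
        est = GradientBoostingClassifier(
            n_estimators=p.get("n_estimators", 200), max_depth=p.get("max_depth", 3),
            learning_rate=p.get("learning_rate", 0.1), random_state=spec.seed,
        )
    elif fam is ModelFamily.SVM:
        est = SVC(C=p.get("C", 1.0), kernel=p.get("kernel", "rbf"),
                  probability=True, random_state=spec.seed)
    elif fam is ModelFamily.NEURAL_NET:
        est = MLPClassifier(
            hidden_layer_sizes=p.get("hidden_layer_sizes", (32,)),
            max_iter=p.get("max_iter", 500), random_state=spec.seed,
        )
    else:  # pragma: no cover
        raise ValueError(f"unsupported family {fam}")
    if fam in _SCALED:
        return SkPipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class CVResult:
    spec: ModelSpec
    fold_accuracies: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def _design(matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    return matrix.values.to_numpy(dtype=float), matrix.y()


def cross_validate(matrix: FeatureMatrix, specs: list[ModelSpec]) -> tuple[list[CVResult], ModelSpec]:
    """Stratified k-fold CV accuracy per spec; returns all results and the
    winner (max mean accuracy, ties by enum order)."""
    X, y = _design(matrix)
    results: list[CVResult] = []
    for spec in specs:
        try:
            est = build_estimator(spec)
        except Exception as exc:  # back end unavailable → skip, don't fail
            logger.warning("skipping %s: %s", spec.family.value, exc)
            continue
        skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
        accs = []
        for tr, te in skf.split(X, y):
            est_f = build_estimator(spec)
            est_f.fit(X[tr], y[tr])
            accs.append(float(np.mean(est_f.predict(X[te]) == y[te])))
        results.append(CVResult(spec=spec, fold_accuracies=accs))
    if not results:
        raise ValueError("no usable model spec")
    order = {f: i for i, f in enumerate(ModelFamily)}
    best = max(results, key=lambda r: (r.mean_accuracy, -order[r.spec.family]))
    return results, best.spec


@dataclass
class TrainedModel:
    estimator: object
    input_manifest: list[str]
    kept_columns: list[str]
    spec: ModelSpec
    weight_config: dict

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        return joblib.load(path)


def train(matrix: FeatureMatrix, spec: ModelSpec | None = None) -> TrainedModel:
    """Fit a model after dropping zero-variance training columns (logged)."""
    spec = spec or ModelSpec()
    X, y = _design(matrix)
    variance = X.var(axis=0)
    kept = [c for c, v in zip(matrix.manifest, variance) if v > 0]
    dropped = [c for c, v in zip(matrix.manifest, variance) if v <= 0]
    if dropped:
        logger.info("dropping %d zero-variance column(s): %s", len(dropped), dropped[:10])
    if not kept:
        raise ValueError("all columns have zero variance")
    est = build_estimator(spec)
    est.fit(matrix.values[kept].to_numpy(dtype=float), y)
    return TrainedModel(
        estimator=est,
        input_manifest=matrix.manifest,
        kept_columns=kept,
        spec=spec,
        weight_config=matrix.config.as_dict(),
    )


@dataclass(frozen=True)
class Prediction:
    doc_id: str
    prob_pos: float
    label: Label
    cutoff: float


def predict(model: TrainedModel, matrix: FeatureMatrix, cutoff: float = 0.5) -> list[Prediction]:
    """Probability-thresholded predictions; positive iff prob_pos > cutoff."""
    missing = [c for c in model.input_manifest if c not in matrix.values.columns]
    extra = [c for c in matrix.values.columns if c not in model.input_manifest]
    if missing or extra:
        raise ValueError(
            f"feature-matrix columns do not match the training manifest "
            f"(missing: {missing[:5]}, extra: {extra[:5]})"
        )
    X = matrix.values[model.kept_columns].to_numpy(dtype=float)
    classes = list(model.estimator.classes_)
    probs = model.estimator.predict_proba(X)[:, classes.index(1)]
    return [
        Prediction(
            doc_id=doc_id,
            prob_pos=float(p),
            label=Label.POSITIVE if p > cutoff else Label.NEGATIVE,
            cutoff=cutoff,
        )
        for doc_id, p in zip(matrix.doc_ids, probs)
    ]


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as NaN", name)
        return math.nan
    return num / den


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    """Standard confusion-matrix metrics; undefined ratios are NaN, never 0."""
    accuracy = _ratio(tp + tn, tp + fp + fn + tn, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        logger.warning("f1 undefined; reported as NaN")
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn, accuracy=accuracy,
                         precision=precision, recall=recall, f1=f1)


def confusion_metrics(predictions: list[Prediction], truth: dict[str, Label]) -> MetricsReport:
    """Compare predictions against true labels (same doc_id sets required)."""
    pred_ids = {p.doc_id for p in predictions}
    if pred_ids != set(truth):
        sym = pred_ids.symmetric_difference(truth)
        raise ValueError(f"doc_id mismatch between predictions and truth: {sorted(sym)[:5]}")
    tp = fp = fn = tn = 0
    for p in predictions:
        actual = truth[p.doc_id]
        if p.label is Label.POSITIVE:
            if actual is Label.POSITIVE:
                tp += 1
            else:
                fp += 1
        else:
            if actual is Label.POSITIVE:
                fn += 1
            else:
                tn += 1
    return metrics_from_counts(tp, fp, fn, tn)
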