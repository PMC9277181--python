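"""End-to-end orchestration: documents → transactions → patterns →
scored feature matrix → trained classifier → predictions and metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier_eval import (
    MetricsReport,
    ModelSpec,
    Prediction,
    TrainedModel,
    confusion_metrics,
    predict,
    train,
)
from .corpus_io import Document, Label, stratified_split
from .external_cohorts import DrugLexicon, match_drugs
from .pattern_mining import Pattern, mine_patterns
from .pattern_scoring import (
    FeatureMatrix,
    ScoredPattern,
    WeightConfig,
    build_feature_matrix,
    score_patterns,
)
from .text_processing import TextConfig, Transaction, process_corpus


@dataclass
class PipelineConfig:
    """All knobs for one end-to-end run.

    ``pattern_itemset_size`` is the largest apriori itemset size used for
    the classifier features.  The default of 1 makes each feature one
    keyword set (which already encodes multi-token combinations up to
    ``text.max_len``); larger values add conjunctions of keyword sets.
    """

    text: TextConfig = field(default_factory=TextConfig)
    weights: WeightConfig = field(default_factory=WeightConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    min_support: float = 0.01
    pattern_itemset_size: int = 1
    cutoff: float = 0.5


@dataclass
class FittedPipeline:
    model: TrainedModel
    scored_patterns: list[ScoredPattern]
    patterns: list[Pattern]
    train_matrix: FeatureMatrix
    config: PipelineConfig
    lexicon: DrugLexicon


def _lexicon_hits(
    transactions: list[Transaction], lexicon: DrugLexicon | None
) -> dict[str, tuple[int, int]]:
    if lexicon is None:
        return {}
    return {t.doc_id: match_drugs(t, lexicon) for t in transactions}


def fit_pipeline(
    train_docs: list[Document],
    lexicon: DrugLexicon | None = None,
    config: PipelineConfig | None = None,
) -> FittedPipeline:
    cfg = config or PipelineConfig()
    transactions = process_corpus(train_docs, cfg.text)
    patterns = mine_patterns(
        transactions, min_support=cfg.min_support, max_pattern_len=cfg.pattern_itemset_size
    )
    scored = score_patterns(patterns, smoothing=cfg.weights.score_smoothing)
    matrix = build_feature_matrix(
        transactions, scored, _lexicon_hits(transactions, lexicon), cfg.weights
    )
    model = train(matrix, cfg.model)
    return FittedPipeline(
        model=model,
        scored_patterns=scored,
        patterns=patterns,
        train_matrix=matrix,
        config=cfg,
        lexicon=lexicon or DrugLexicon(),
    )


def transform_documents(fitted: FittedPipeline, docs: list[Document]) -> FeatureMatrix:
    """Feature matrix for new documents using the fitted pattern set."""
    transactions = process_corpus(docs, fitted.config.text)
    return build_feature_matrix(
        transactions,
        fitted.scored_patterns,
        _lexicon_hits(transactions, fitted.lexicon),
        fitted.config.weights,
    )


def predict_documents(
    fitted: FittedPipeline, docs: list[Document], cutoff: float | None = None
) -> list[Prediction]:
    matrix = transform_documents(fitted, docs)
    return predict(fitted.model, matrix, fitted.config.cutoff if cutoff is None else cutoff)


@dataclass
class EvaluationResult:
    fitted: FittedPipeline
    predictions: list[Prediction]
    metrics: MetricsReport


def evaluate_holdout(
    corpus: list[Document],
    lexicon: DrugLexicon | None = None,
    config: PipelineConfig | None = None,
    train_fraction: float = 0.8,
    split_seed: int = 0,
) -> EvaluationResult:
    """Stratified split, fit on train, score the held-out documents."""
    split = stratified_split(corpus, train_fraction=train_fraction, seed=split_seed)
    fitted = fit_pipeline(split.train, lexicon, config)
    preds = predict_documents(fitted, split.test)
    truth = {d.doc_id: d.label for d in split.test}
    return EvaluationResult(
        fitted=fitted, predictions=preds, metrics=confusion_metrics(preds, truth)
    )
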