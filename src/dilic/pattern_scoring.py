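"""Class-ratio scoring of mined patterns and assembly of the weighted
document × pattern feature matrix.

A pattern's class score is its (smoothed) support in one class divided by
its total smoothed support:

    class_score_pos = (support_pos + s) / (support_pos + support_neg + 2s)

with pseudo-count ``s`` keeping single-class patterns off the {0,1}
boundary.  The two class scores always sum to 1.

A document's total weight combines, over the keyword sets present in it
(presence indicator key_i ∈ {0,1}), four terms — frequency, length, and
the FDA/SIDER lexicon boosts:

    W_T = Σ w_freq·freq_i·key_i + Σ w_len·len_i·key_i
        + w_fda·fda_hits + w_sider·sider_hits

Feature-matrix cells carry per-pattern resolution: cell(d, p) =
class_score_pos(p) × (w_freq·freq_{d,p} + w_len·len_p) when pattern p is
contained in document d, else 0; two reserved columns hold the weighted
lexicon hits and one holds W_T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus_io import Label
from .pattern_mining import Pattern
from .text_processing import SEPARATOR, Transaction

logger = logging.getLogger(__name__)

FDA_COLUMN = "__fda_hits__"
SIDER_COLUMN = "__sider_hits__"
TOTAL_WEIGHT_COLUMN = "__W_T__"
RESERVED_COLUMNS = (FDA_COLUMN, SIDER_COLUMN, TOTAL_WEIGHT_COLUMN)

#: joins the (possibly multi-token) items of a multi-item pattern into a column key
ITEM_JOIN = "&"


@dataclass(frozen=True)
class WeightConfig:
    w_freq: float = 1.0
    w_len: float = 1.0
    w_fda: float = 2.0
    w_sider: float = 2.0
    score_smoothing: float = 1.0

    def __post_init__(self) -> None:
        for name in ("w_freq", "w_len", "w_fda", "w_sider", "score_smoothing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "w_freq": self.w_freq,
            "w_len": self.w_len,
            "w_fda": self.w_fda,
            "w_sider": self.w_sider,
            "score_smoothing": self.score_smoothing,
        }


@dataclass(frozen=True)
class ScoredPattern:
    pattern: Pattern
    class_score_pos: float
    class_score_neg: float

    @property
    def key(self) -> str:
        return ITEM_JOIN.join(sorted(self.pattern.items))

    @property
    def token_length(self) -> int:
        """Total token count across the pattern's keyword-set items
        (singleton 1, pair 2, triplet 3 for single-item patterns)."""
        return sum(item.count(SEPARATOR) + 1 for item in self.pattern.items)


def score_pattern(pattern: Pattern, smoothing: float = 1.0) -> ScoredPattern:
    """Class-ratio score with optional pseudo-count smoothing."""
    total = pattern.support_pos + pattern.support_neg
    if total <= 0:
        raise ValueError(f"pattern {set(pattern.items)} has zero total support")
    denom = total + 2.0 * smoothing
    pos = (pattern.support_pos + smoothing) / denom
    return ScoredPattern(pattern=pattern, class_score_pos=pos, class_score_neg=1.0 - pos)


def score_patterns(patterns: list[Pattern], smoothing: float = 1.0) -> list[ScoredPattern]:
    return [score_pattern(p, smoothing) for p in patterns]


def rank_patterns(scored: list[ScoredPattern]) -> list[ScoredPattern]:
    """Descending positive-class score; ties broken by total support
    (desc), token length (desc), then items — deterministic."""
    return sorted(
        scored,
        key=lambda s: (
            -s.class_score_pos,
            -s.pattern.support,
            -s.token_length,
            tuple(sorted(s.pattern.items)),
        ),
    )


def compute_total_weight(
    row: list[dict],
    config: WeightConfig,
    fda_hits: int = 0,
    sider_hits: int = 0,
) -> float:
    """Total document weight from per-keyword-set components.

    ``row`` holds one dict per keyword set i with keys ``freq`` (occurrence
    count), ``len`` (token length) and ``key`` (presence indicator 0/1).
    Absent keyword sets (key 0) contribute nothing to any term.
    """
    total = 0.0
    for comp in row:
        key = comp["key"]
        if key not in (0, 1):
            raise ValueError("key_i must be 0 or 1")
        freq, length = comp["freq"], comp["len"]
        if freq < 0 or length < 0:
            raise ValueError("negative component")
        total += key * (config.w_freq * freq + config.w_len * length)
    if fda_hits < 0 or sider_hits < 0:
        raise ValueError("negative lexicon hit count")
    return total + config.w_fda * fda_hits + config.w_sider * sider_hits


@dataclass
class FeatureMatrix:
    """documents × (patterns + fda + sider + W_T) weight matrix."""

    values: pd.DataFrame  # index doc_id, float columns
    labels: pd.Series  # index doc_id, values Label
    config: WeightConfig

    @property
    def doc_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def pattern_keys(self) -> list[str]:
        return [c for c in self.values.columns if c not in RESERVED_COLUMNS]

    @property
    def manifest(self) -> list[str]:
        return list(self.values.columns)

    def y(self) -> np.ndarray:
        return np.array([1 if l is Label.POSITIVE else 0 for l in self.labels])

    def write_triplets(self, path) -> None:
        """Sparse triplet TSV (doc_id, column_key, value), zero cells omitted."""
        sub = self.values.stack()
        sub = sub[sub != 0]
        out = sub.reset_index()
        out.columns = ["doc_id", "column_key", "value"]
        out.to_csv(path, sep="\t", index=False)

    def write_manifest(self, path) -> None:
        pd.DataFrame({"column_key": self.manifest}).to_csv(path, sep="\t", index=False)


def _pattern_freq(transaction: Transaction, items: frozenset[str]) -> int:
    """Occurrence count of a complete pattern in a document: the minimum
    item frequency over its items (0 if any item is absent)."""
    freqs = [transaction.item_freq.get(i, 0) for i in items]
    return min(freqs) if freqs else 0


def build_feature_matrix(
    transactions: list[Transaction],
    scored_patterns: list[ScoredPattern],
    lexicon_hits: dict[str, tuple[int, int]] | None,
    config: WeightConfig | None = None,
) -> FeatureMatrix:
    """Assemble the weighted feature matrix.

    ``lexicon_hits`` maps doc_id → (fda_hits, sider_hits); None means no
    external cohorts were supplied (both columns zero).
    """
    cfg = config or WeightConfig()
    if not scored_patterns:
        raise ValueError("scored pattern list is empty")
    hits = lexicon_hits or {}

    keys = [sp.key for sp in scored_patterns]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate pattern keys in scored pattern list")
    order = np.argsort(keys, kind="stable")
    scored_sorted = [scored_patterns[i] for i in order]
    columns = [sp.key for sp in scored_sorted] + list(RESERVED_COLUMNS)

    rows = np.zeros((len(transactions), len(columns)), dtype=float)
    any_pattern_hit = False
    for r, t in enumerate(transactions):
        wt = 0.0
        for c, sp in enumerate(scored_sorted):
            freq = _pattern_freq(t, sp.pattern.items)
            if freq > 0:
                base = cfg.w_freq * freq + cfg.w_len * sp.token_length
                rows[r, c] = sp.class_score_pos * base
                wt += base
                any_pattern_hit = True
        fda, sider = hits.get(t.doc_id, (0, 0))
        rows[r, -3] = cfg.w_fda * fda
        rows[r, -2] = cfg.w_sider * sider
        rows[r, -1] = wt + cfg.w_fda * fda + cfg.w_sider * sider

    if transactions and not any_pattern_hit:
        raise ValueError(
            "no pattern matched any transaction — pattern and transaction "
            "vocabularies disagree (different separator or normalizer?)"
        )
    index = pd.Index([t.doc_id for t in transactions], name="doc_id")
    values = pd.DataFrame(rows, index=index, columns=columns)
    labels = pd.Series([t.label for t in transactions], index=index, name="label")
    return FeatureMatrix(values=values, labels=labels, config=cfg)
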