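"""Turn titles+abstracts into transactions of keyword sets.

The transformation per document: segment sentences, tokenize words, keep
nouns and adjectives, drop stop words and blocklisted terms, normalize
each survivor (lowercase → lemmatize → stem), then emit every unordered
combination of distinct normalized tokens within a sentence, for sizes
1..max_len (singletons, pairs, triplets by default).  Multiplicities
accumulate across the sentences of a document, giving the per-item
frequencies used later as weights.

Keyword sets have one canonical form: lexicographically sorted items
joined by a separator (default ``|``), so the same combination always
maps to the same string regardless of word order in the sentence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .corpus_io import Document, Label
from . import nlp

logger = logging.getLogger(__name__)

SEPARATOR = "|"


@dataclass(frozen=True)
class Token:
    surface: str
    lemma_stem: str
    pos: str  # NOUN / ADJ / OTHER


@dataclass
class TextConfig:
    """Knobs for transaction building.

    max_len: largest keyword-set size (tokens per combination).
    sentence_token_cap: sentences with more surviving tokens are truncated
        to the first ``cap`` before combination generation (C(n,3) growth).
    stopwords: words removed regardless of POS tag.
    blocklist: additional user-supplied unwanted terms (compared on the
        normalized form as well as the raw lowercased surface).
    """

    max_len: int = 3
    sentence_token_cap: int = 25
    stopwords: frozenset[str] = nlp.DEFAULT_STOPWORDS
    blocklist: frozenset[str] = frozenset()
    separator: str = SEPARATOR


@dataclass
class Transaction:
    doc_id: str
    label: Label
    item_freq: Counter = field(default_factory=Counter)

    @property
    def items(self) -> set[str]:
        return set(self.item_freq)


def canonical_key(items: tuple[str, ...] | list[str] | set[str], separator: str = SEPARATOR) -> str:
    """Canonical string for an unordered keyword set."""
    return separator.join(sorted(set(items)))


segment_sentences = nlp.segment_sentences


def extract_tokens(sentence: str, stopwords: frozenset[str] = nlp.DEFAULT_STOPWORDS) -> list[Token]:
    """Tokenize one sentence, keeping normalized nouns and adjectives.

    Stop words are removed from the surviving noun/adjective list as a
    safety net (closed-class words rarely tag as NOUN/ADJ anyway).
    """
    out: list[Token] = []
    for surface in nlp.word_tokenize(sentence):
        low = surface.lower()
        if low in stopwords:
            continue
        pos = nlp.pos_tag(surface)
        if pos not in (nlp.NOUN, nlp.ADJ):
            continue
        lemma_stem = nlp.normalize_token(surface)
        if not lemma_stem:
            continue
        out.append(Token(surface=surface, lemma_stem=lemma_stem, pos=pos))
    return out


def generate_keyword_sets(tokens: list[Token], max_len: int, separator: str = SEPARATOR) -> Counter:
    """All unordered combinations of distinct lemma_stems, sizes 1..max_len.

    Duplicate lemma_stems within the sentence are collapsed first (sets,
    not bags).  Returns a Counter keyed by canonical keyword-set string.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    distinct = sorted(set(t.lemma_stem for t in tokens))
    out: Counter = Counter()
    for k in range(1, min(len(distinct), max_len) + 1):
        for combo in combinations(distinct, k):
            out[separator.join(combo)] += 1
    return out


def process_document(doc: Document, config: TextConfig | None = None) -> Transaction:
    """Build the Transaction for one document (title and abstract merged).

    Each sentence of the title and the abstract contributes its keyword
    sets independently; a keyword set's frequency is the number of
    sentence-level occurrences across the whole document.
    """
    cfg = config or TextConfig()
    freq: Counter = Counter()
    for text in (doc.title, doc.abstract):
        for sentence in nlp.segment_sentences(text):
            tokens = extract_tokens(sentence, cfg.stopwords)
            if cfg.blocklist:
                tokens = [
                    t for t in tokens
                    if t.lemma_stem not in cfg.blocklist and t.surface.lower() not in cfg.blocklist
                ]
            if len(tokens) > cfg.sentence_token_cap:
                logger.warning(
                    "document %s: sentence with %d surviving tokens truncated to %d",
                    doc.doc_id, len(tokens), cfg.sentence_token_cap,
                )
                # cap on distinct stems, keeping first occurrences
                seen: list[Token] = []
                stems: set[str] = set()
                for t in tokens:
                    if t.lemma_stem not in stems:
                        stems.add(t.lemma_stem)
                        seen.append(t)
                    if len(stems) == cfg.sentence_token_cap:
                        break
                tokens = seen
            freq.update(generate_keyword_sets(tokens, cfg.max_len, cfg.separator))
    if not freq:
        logger.warning("document %s yielded no keyword sets", doc.doc_id)
    return Transaction(doc_id=doc.doc_id, label=doc.label, item_freq=freq)


def process_corpus(docs: list[Document], config: TextConfig | None = None) -> list[Transaction]:
    cfg = config or TextConfig()
    return [process_document(d, cfg) for d in docs]


def write_transactions(transactions: list[Transaction], path) -> None:
    """Interchange TSV: doc_id, label, item (canonical), frequency."""
    import pandas as pd

    rows = [
        (t.doc_id, t.label.value, item, n)
        for t in transactions
        for item, n in sorted(t.item_freq.items())
    ]
    pd.DataFrame(rows, columns=["doc_id", "label", "item", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


def read_transactions(path) -> list[Transaction]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"doc_id": str, "label": str, "item": str})
    out: dict[str, Transaction] = {}
    for row in df.itertuples(index=False):
        t = out.setdefault(
            str(row.doc_id), Transaction(doc_id=str(row.doc_id), label=Label.parse(row.label))
        )
        t.item_freq[row.item] = int(row.frequency)
    return list(out.values())
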