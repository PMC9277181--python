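"""Synthetic labelled corpora and drug-cohort tables with planted
class-discriminative structure.

The generator emulates the shape of a curated adverse-event literature
corpus: two document classes over a shared noun-like vocabulary, a set of
planted keyword patterns (1–3 tokens, inserted within single sentences)
that occur in positive documents with probability ``p`` and in negative
documents with ``p / planted_enrichment``, and a drug lexicon in which a
known subset carries a DILI adverse-event flag and is mentioned
preferentially in positive documents.

Each planted pattern's proper sub-combinations are additionally injected
class-neutrally (same probability in both classes).  Real sub-phrases of
a discriminative phrase also occur on their own in unrelated contexts;
without this, every subset of a planted pattern would inherit the full
pattern's enrichment exactly and the full pattern would carry no signal
beyond its own parts.

Vocabulary tokens are synthetic noun-like strings (``tokNNN``, planted
``kwNNN``, drugs ``drugNN``) so POS tagging degenerates predictably; all
randomness flows from one seeded generator and the ground truth is
returned alongside the corpus for assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .corpus_io import Document, Label
from .external_cohorts import normalize_drug_name
from .text_processing import canonical_key
from . import nlp


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 500
    n_neg: int = 500
    vocab_size: int = 400
    n_planted_patterns: int = 10
    planted_enrichment: float = 8.0
    planted_occurrence_prob: float = 0.4
    subset_background_prob: float = 0.2
    n_drugs: int = 20
    dili_drug_fraction: float = 0.5
    drug_mention_prob_pos: float = 0.12
    drug_mention_prob_neg: float = 0.04
    sentences_per_doc: tuple[int, int] = (3, 6)
    tokens_per_sentence: tuple[int, int] = (4, 8)
    seed: int = 42

    def __post_init__(self) -> None:
        for p in (
            self.planted_occurrence_prob, self.subset_background_prob,
            self.dili_drug_fraction, self.drug_mention_prob_pos,
            self.drug_mention_prob_neg,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_enrichment < 1:
            raise ValueError("planted_enrichment must be >= 1")
        if min(self.n_pos, self.n_neg, self.vocab_size, self.n_drugs) < 0:
            raise ValueError("counts must be non-negative")
        # each pattern needs up to 3 dedicated tokens
        if self.vocab_size < 4 * self.n_planted_patterns:
            raise ValueError(
                "vocab_size too small for the requested planted patterns "
                f"(need >= {4 * self.n_planted_patterns})"
            )


@dataclass
class GroundTruth:
    planted_patterns: list[tuple[str, ...]]
    planted_keys: list[str]  # canonical normalized keyword-set strings
    dili_drugs: list[str]
    all_drugs: list[str]
    config: SynthConfig


def _pattern_tokens(config: SynthConfig) -> list[tuple[str, ...]]:
    """Disjoint planted patterns with lengths cycling 1, 2, 3."""
    patterns = []
    next_id = 0
    for i in range(config.n_planted_patterns):
        length = (i % 3) + 1
        patterns.append(tuple(f"kw{next_id + j:03d}" for j in range(length)))
        next_id += length
    return patterns


def generate_corpus(config: SynthConfig | None = None) -> tuple[list[Document], GroundTruth]:
    """Generate the labelled corpus and its ground-truth record."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    background = [f"tok{i:03d}" for i in range(cfg.vocab_size)]
    patterns = _pattern_tokens(cfg)
    drugs = [f"drug{i:02d}" for i in range(cfg.n_drugs)]
    n_dili = round(cfg.n_drugs * cfg.dili_drug_fraction)
    dili_drugs = drugs[:n_dili]

    subsets = [
        [sub for k in range(1, len(pat)) for sub in combinations(pat, k)]
        for pat in patterns
    ]
    p_pos = cfg.planted_occurrence_prob
    p_neg = p_pos / cfg.planted_enrichment

    docs: list[Document] = []
    for label, n_docs, planted_p, drug_p in (
        (Label.POSITIVE, cfg.n_pos, p_pos, cfg.drug_mention_prob_pos),
        (Label.NEGATIVE, cfg.n_neg, p_neg, cfg.drug_mention_prob_neg),
    ):
        for d in range(n_docs):
            n_sent = int(rng.integers(cfg.sentences_per_doc[0], cfg.sentences_per_doc[1] + 1))
            sentences = [
                list(rng.choice(background, size=int(rng.integers(
                    cfg.tokens_per_sentence[0], cfg.tokens_per_sentence[1] + 1))))
                for _ in range(n_sent)
            ]
            # Planted phrases occupy their own short sentences.  Keyword
            # sets are formed within a sentence, so dropping two planted
            # phrases into the same sentence would create conjunction
            # features more class-enriched than either phrase alone.
            extra: list[list[str]] = []
            for pat, subs in zip(patterns, subsets):
                if rng.random() < planted_p:
                    extra.append(list(pat) + list(rng.choice(background, size=2)))
                for sub in subs:  # class-neutral sub-combination background
                    if rng.random() < cfg.subset_background_prob:
                        extra.append(list(sub) + list(rng.choice(background, size=2)))
            for sent in extra:
                sentences.insert(int(rng.integers(len(sentences) + 1)), sent)
            for i, drug in enumerate(drugs):
                p = drug_p if drug in dili_drugs else cfg.drug_mention_prob_neg
                if rng.random() < p:
                    sentences[int(rng.integers(len(sentences)))].append(drug)
            text = [" ".join(s).capitalize() + "." for s in sentences]
            prefix = "pos" if label is Label.POSITIVE else "neg"
            docs.append(
                Document(
                    doc_id=f"{prefix}{d:05d}",
                    title=text[0],
                    abstract=" ".join(text[1:]),
                    label=label,
                )
            )

    truth = GroundTruth(
        planted_patterns=patterns,
        planted_keys=[canonical_key([nlp.normalize_token(t) for t in pat]) for pat in patterns],
        dili_drugs=dili_drugs,
        all_drugs=drugs,
        config=cfg,
    )
    return docs, truth


def generate_cohorts(
    config: SynthConfig | None = None, truth: GroundTruth | None = None
):
    """FDA-style and SIDER-style cohort tables as pandas DataFrames.

    Every drug appears in both tables; exactly
    ``round(n_drugs * dili_drug_fraction)`` carry a DILI term in the
    adverse-event field.  If ``truth`` is given its drug list is reused so
    the cohorts align with the corpus.
    """
    import pandas as pd

    cfg = config or SynthConfig()
    if truth is not None:
        drugs, dili = truth.all_drugs, set(truth.dili_drugs)
    else:
        drugs = [f"drug{i:02d}" for i in range(cfg.n_drugs)]
        dili = set(drugs[: round(cfg.n_drugs * cfg.dili_drug_fraction)])

    def table(dili_term: str, benign: str) -> "pd.DataFrame":
        rows = []
        for i, name in enumerate(drugs):
            events = f"nausea; {dili_term}; rash" if name in dili else f"headache; {benign}"
            rows.append((name, f"Brand{i:02d}", f"CID{i:05d}", events))
        return pd.DataFrame(
            rows, columns=["drug_name", "brand_names", "compound_id", "adverse_events"]
        )

    fda = table("hepatotoxicity", "dizziness")
    sider = table("drug-induced liver injury", "fatigue")
    return fda, sider


def write_fixture_set(config: SynthConfig, out_dir) -> GroundTruth:
    """Write corpus.tsv, fda.tsv, sider.tsv and ground_truth.json to a directory."""
    import json
    from pathlib import Path

    from .corpus_io import write_corpus

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs, truth = generate_corpus(config)
    write_corpus(docs, out / "corpus.tsv")
    fda, sider = generate_cohorts(config, truth)
    fda.to_csv(out / "fda.tsv", sep="\t", index=False)
    sider.to_csv(out / "sider.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "planted_patterns": [list(p) for p in truth.planted_patterns],
                "planted_keys": truth.planted_keys,
                "dili_drugs": truth.dili_drugs,
                "all_drugs": truth.all_drugs,
                "seed": config.seed,
            },
            indent=2,
        )
    )
    return truth
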