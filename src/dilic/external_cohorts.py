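"""Drug-cohort tables and the DILI-flagged drug lexicon.

Two external tables feed the pipeline: an FDA-style approved-drug list
and a SIDER-style side-effect table.  A record is DILI-flagged when any
configured DILI term appears (case-insensitive substring) in its
adverse-event/warning field.  Flagged generic and brand names, normalized
with the same lowercase→lemmatize→stem normalizer as the text pipeline,
form the lexicon that is matched against document keyword sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from . import nlp
from .text_processing import SEPARATOR, Transaction, canonical_key

logger = logging.getLogger(__name__)


class Source(Enum):
    FDA = "FDA"
    SIDER = "SIDER"


DEFAULT_DILI_TERMS = frozenset(
    {
        "drug-induced liver injury",
        "dili",
        "hepatotoxicity",
        "liver injury",
        "hepatic failure",
    }
)

DEFAULT_COHORT_COLUMNS = {
    "drug_name": "drug_name",
    "brand_names": "brand_names",
    "compound_id": "compound_id",
    "adverse_events": "adverse_events",
}


@dataclass(frozen=True)
class DrugRecord:
    generic_name: str
    brand_names: tuple[str, ...]
    compound: str
    source: Source
    dili_flag: bool

    def __post_init__(self) -> None:
        if not self.generic_name:
            raise ValueError("generic_name must be non-empty")


@dataclass
class DrugLexicon:
    """Normalized names of DILI-flagged drugs with per-name source provenance."""

    name_to_source: dict[str, set[Source]] = field(default_factory=dict)

    @property
    def names(self) -> set[str]:
        return set(self.name_to_source)

    def __len__(self) -> int:
        return len(self.name_to_source)


def normalize_drug_name(name: str, separator: str = SEPARATOR) -> str:
    """Normalize a drug name token-by-token into canonical keyword-set form.

    Multi-word names become the corresponding pair/triplet item, so an
    exact match against document keyword sets is possible.
    """
    tokens = [nlp.normalize_token(t) for t in nlp.word_tokenize(name)]
    tokens = [t for t in tokens if t]
    return canonical_key(tokens, separator) if tokens else ""


def load_cohort(
    path: str | Path,
    source: Source,
    columns: dict[str, str] | None = None,
    dili_terms: frozenset[str] = DEFAULT_DILI_TERMS,
) -> list[DrugRecord]:
    """Parse a cohort table and derive each record's DILI flag."""
    cols = {**DEFAULT_COHORT_COLUMNS, **(columns or {})}
    if not Path(path).exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in (cols["drug_name"], cols["adverse_events"]) if c not in df.columns]
    if missing:
        raise KeyError(f"missing column(s) in {path}: {', '.join(missing)}")
    if df.empty:
        logger.warning("cohort file %s is empty", path)
        return []
    terms = [t.lower() for t in dili_terms]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        name = str(d[cols["drug_name"]]).strip()
        if not name:
            continue
        brands = tuple(
            b.strip()
            for b in str(d.get(cols["brand_names"], "")).split(";")
            if b.strip()
        )
        ae = str(d.get(cols["adverse_events"], "")).lower()
        records.append(
            DrugRecord(
                generic_name=name,
                brand_names=brands,
                compound=str(d.get(cols["compound_id"], "")).strip(),
                source=source,
                dili_flag=any(term in ae for term in terms),
            )
        )
    return records


def build_lexicon(records: list[DrugRecord], include_brands: bool = True) -> DrugLexicon:
    """Union of normalized generic (and optionally brand) names of flagged records."""
    lex = DrugLexicon()
    for rec in records:
        if not rec.dili_flag:
            continue
        names = [rec.generic_name] + (list(rec.brand_names) if include_brands else [])
        for raw in names:
            norm = normalize_drug_name(raw)
            if norm:
                lex.name_to_source.setdefault(norm, set()).add(rec.source)
    if not lex.name_to_source:
        logger.warning("drug lexicon is empty (no DILI-flagged records)")
    return lex


def match_drugs(transaction: Transaction, lexicon: DrugLexicon) -> tuple[int, int]:
    """Count distinct lexicon drugs present in a transaction, per source.

    A hit is an exact match between a lexicon name (canonical keyword-set
    form) and one of the transaction's items — no partial-string matches
    inside longer tokens.
    """
    fda = sider = 0
    if not lexicon.name_to_source:
        return 0, 0
    for name in transaction.items & lexicon.names:
        sources = lexicon.name_to_source[name]
        if Source.FDA in sources:
            fda += 1
        if Source.SIDER in sources:
            sider += 1
    return fda, sider


def write_lexicon(lexicon: DrugLexicon, path: str | Path) -> None:
    rows = [
        (name, ";".join(sorted(s.value for s in sources)))
        for name, sources in sorted(lexicon.name_to_source.items())
    ]
    pd.DataFrame(rows, columns=["name", "sources"]).to_csv(path, sep="\t", index=False)
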