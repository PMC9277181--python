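"""Corpus and prediction I/O plus the stratified discovery split.

Corpora are delimited text tables (TSV by default) with a header row and
configurable column names; readers and writers accept ``-`` for
stdin/stdout.  The split shuffles within each label class with a seeded
generator and slices, so the class balance of the input is preserved in
both halves and the operation is reproducible.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd


class Label(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, raw: str) -> "Label":
        s = str(raw).strip().lower()
        if s in ("positive", "pos", "1", "true", "yes"):
            return cls.POSITIVE
        if s in ("negative", "neg", "0", "false", "no"):
            return cls.NEGATIVE
        if s in ("", "unknown", "na", "nan", "none", "?"):
            return cls.UNKNOWN
        raise ValueError(f"unrecognized label: {raw!r}")


@dataclass(frozen=True)
class Document:
    """One article: identifier, title, abstract, optional class label."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("document requires a non-empty doc_id")
        if not self.title.strip() and not self.abstract.strip():
            raise ValueError(f"document {self.doc_id!r}: title and abstract both empty")

    @property
    def text(self) -> str:
        return f"{self.title}\n{self.abstract}".strip()


@dataclass(frozen=True)
class CorpusSplit:
    train: list[Document]
    test: list[Document]
    train_fraction: float
    seed: int


DEFAULT_COLUMNS = {"id": "id", "title": "title", "abstract": "abstract", "label": "label"}


class DuplicateDocumentError(ValueError):
    def __init__(self, duplicates: list[str]):
        self.duplicates = duplicates
        super().__init__(f"duplicate doc_id(s): {', '.join(duplicates)}")


def _open(path: str | Path, mode: str) -> IO[str]:
    if str(path) == "-":
        return sys.stdin if "r" in mode else sys.stdout
    return open(path, mode, encoding="utf-8", newline="")


def read_corpus(
    path: str | Path,
    delimiter: str = "\t",
    columns: dict[str, str] | None = None,
) -> list[Document]:
    """Read a corpus table into Documents.

    ``columns`` maps the logical fields (id/title/abstract/label) to the
    header names used in the file.  Labels are parsed case-insensitively;
    a missing label column yields UNKNOWN documents.  Duplicate ids are a
    hard error that names every offender.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    if str(path) != "-" and not Path(path).exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(_open(path, "r"), sep=delimiter, dtype=str, keep_default_na=False)
    required = [cols["id"], cols["title"], cols["abstract"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"missing column(s) in {path}: {', '.join(missing)}")
    has_label = cols["label"] in df.columns

    ids = df[cols["id"]].astype(str)
    empty_ids = ids.str.strip() == ""
    if empty_ids.any():
        raise ValueError(f"{int(empty_ids.sum())} row(s) with missing id in {path}")
    counts = ids.value_counts()
    dups = sorted(counts[counts > 1].index.tolist())
    if dups:
        raise DuplicateDocumentError(dups)

    docs = []
    for _, row in df.iterrows():
        docs.append(
            Document(
                doc_id=str(row[cols["id"]]).strip(),
                title=str(row[cols["title"]]),
                abstract=str(row[cols["abstract"]]),
                label=Label.parse(row[cols["label"]]) if has_label else Label.UNKNOWN,
            )
        )
    return docs


def write_corpus(
    docs: Iterable[Document],
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    df = pd.DataFrame(
        {
            "id": [d.doc_id for d in docs],
            "title": [d.title for d in docs],
            "abstract": [d.abstract for d in docs],
            "label": [d.label.value for d in docs],
        }
    )
    for col in ("id", "title", "abstract"):
        bad = df[col].str.contains(delimiter, regex=False) | df[col].str.contains("\n", regex=False)
        if bad.any():
            raise ValueError(
                f"field {col!r} contains the delimiter or a newline in "
                f"{int(bad.sum())} row(s); escape or clean the input"
            )
    df.to_csv(_open(path, "w"), sep=delimiter, index=False)


def write_predictions(rows: Iterable[tuple[str, float, str]], path: str | Path) -> None:
    """Write predictions as TSV: doc_id, probability, predicted_label."""
    df = pd.DataFrame(rows, columns=["doc_id", "probability", "predicted_label"])
    df.to_csv(_open(path, "w"), sep="\t", index=False)


def stratified_split(
    corpus: list[Document],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> CorpusSplit:
    """Split a labelled corpus into train/test preserving the class ratio.

    Within each class the documents are shuffled with a seeded generator
    and the first ``floor(train_fraction * class_size)`` go to train.
    Deterministic for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    unknown = [d.doc_id for d in corpus if d.label is Label.UNKNOWN]
    if unknown:
        raise ValueError(f"unlabelled document(s) in split input: {unknown[:5]}")

    rng = np.random.default_rng(seed)
    train: list[Document] = []
    test: list[Document] = []
    for label in (Label.POSITIVE, Label.NEGATIVE):
        members = [d for d in corpus if d.label is label]
        if len(members) < 2:
            raise ValueError(f"class {label.value} has fewer than 2 members")
        order = rng.permutation(len(members))
        n_train = math.floor(train_fraction * len(members) + 1e-9)
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return CorpusSplit(train=train, test=test, train_fraction=train_fraction, seed=seed)
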