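import pytest
from hypothesis import given, settings, strategies as st

from dilic.corpus_io import (
    Document,
    DuplicateDocumentError,
    Label,
    read_corpus,
    stratified_split,
    write_corpus,
)


def _write(tmp_path, rows, header="id\ttitle\tabstract\tlabel"):
    p = tmp_path / "corpus.tsv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


class TestReadCorpus:
    def test_parses_rows_and_labels_case_insensitively(self, tmp_path):
        p = _write(tmp_path, [
            "a\tT1\tA1\tpositive",
            "b\tT2\tA2\tNEGATIVE",
            "c\tT3\tA3\tPositive",
        ])
        docs = read_corpus(p)
        assert len(docs) == 3
        assert [d.label for d in docs].count(Label.POSITIVE) == 2
        assert [d.label for d in docs].count(Label.NEGATIVE) == 1

    def test_empty_title_with_abstract_accepted(self, tmp_path):
        p = _write(tmp_path, ["a\t\tsome abstract\tpositive"])
        (doc,) = read_corpus(p)
        assert doc.title == "" and doc.abstract == "some abstract"

    def test_duplicate_ids_rejected_naming_offenders(self, tmp_path):
        p = _write(tmp_path, [
            "A1\tt\ta\tpositive",
            "A1\tt\ta\tnegative",
            "B2\tt\ta\tpositive",
        ])
        with pytest.raises(DuplicateDocumentError, match="A1"):
            read_corpus(p)

    def test_missing_column_and_missing_file(self, tmp_path):
        p = _write(tmp_path, ["a\tt\tpositive"], header="id\ttitle\tlabel")
        with pytest.raises(KeyError, match="abstract"):
            read_corpus(p)
        with pytest.raises(FileNotFoundError):
            read_corpus(tmp_path / "nope.tsv")

    def test_both_fields_empty_rejected(self):
        with pytest.raises(ValueError, match="both empty"):
            Document(doc_id="x", title="", abstract="")

    def test_round_trip(self, tmp_path):
        p = _write(tmp_path, [
            "a\tTitle one\tAbstract one\tpositive",
            "b\tTitle two\tAbstract two\tunknown",
        ])
        docs = read_corpus(p)
        out = tmp_path / "copy.tsv"
        write_corpus(docs, out)
        assert read_corpus(out) == docs


def _corpus(n_pos, n_neg):
    docs = [Document(f"p{i}", title="t", label=Label.POSITIVE) for i in range(n_pos)]
    docs += [Document(f"n{i}", title="t", label=Label.NEGATIVE) for i in range(n_neg)]
    return docs


class TestStratifiedSplit:
    def test_balanced_80_20(self):
        split = stratified_split(_corpus(100, 100), 0.8, seed=7)
        train_pos = sum(d.label is Label.POSITIVE for d in split.train)
        test_pos = sum(d.label is Label.POSITIVE for d in split.test)
        assert (train_pos, len(split.train) - train_pos) == (80, 80)
        assert (test_pos, len(split.test) - test_pos) == (20, 20)

    def test_deterministic_for_fixed_seed(self):
        corpus = _corpus(50, 50)
        a = stratified_split(corpus, 0.8, seed=3)
        b = stratified_split(corpus, 0.8, seed=3)
        assert [d.doc_id for d in a.train] == [d.doc_id for d in b.train]
        assert [d.doc_id for d in a.test] == [d.doc_id for d in b.test]

    def test_discovery_cohort_class_counts(self):
        # 14,203 discovery articles, 7,177 positive / 7,026 negative at 0.8
        split = stratified_split(_corpus(7177, 7026), 0.8, seed=0)
        train_pos = sum(d.label is Label.POSITIVE for d in split.train)
        test_pos = sum(d.label is Label.POSITIVE for d in split.test)
        assert train_pos == 5741
        assert len(split.train) - train_pos == 5620
        assert test_pos == 1436
        assert len(split.test) - test_pos == 1406
        assert len(split.train) == 11361

    def test_rejects_unknown_labels_and_tiny_classes(self):
        docs = _corpus(5, 5) + [Document("u", title="t", label=Label.UNKNOWN)]
        with pytest.raises(ValueError, match="unlabelled"):
            stratified_split(docs, 0.8, seed=0)
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(_corpus(1, 10), 0.8, seed=0)
        with pytest.raises(ValueError, match="train_fraction"):
            stratified_split(_corpus(5, 5), 1.2, seed=0)

    @settings(derandomize=True, max_examples=50)
    @given(
        n_pos=st.integers(2, 200),
        n_neg=st.integers(2, 200),
        frac=st.floats(0.1, 0.9),
        seed=st.integers(0, 1000),
    )
    def test_partition_and_per_class_balance(self, n_pos, n_neg, frac, seed):
        corpus = _corpus(n_pos, n_neg)
        split = stratified_split(corpus, frac, seed=seed)
        all_ids = {d.doc_id for d in corpus}
        train_ids = {d.doc_id for d in split.train}
        test_ids = {d.doc_id for d in split.test}
        assert train_ids | test_ids == all_ids and not train_ids & test_ids
        for label, n in ((Label.POSITIVE, n_pos), (Label.NEGATIVE, n_neg)):
            k = sum(d.label is label for d in split.train)
            assert abs(k - frac * n) <= 1
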