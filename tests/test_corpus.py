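"""Data model, BIO coding and file-format round trips."""

import itertools
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btner.corpus import (
    DEFAULT_REGISTRY,
    AnnotatedSentence,
    CorpusError,
    Document,
    EntitySpan,
    EntityTypeRegistry,
    bio_decode,
    bio_encode,
    bio_label_alphabet,
    corpus_statistics,
    read_conll,
    read_standoff,
    split_sentences,
    write_conll,
    write_standoff,
)
from btner.synth import SynthConfig, generate_corpus

DATA = Path(__file__).parent / "data"


class TestBioCoding:
    def test_no_spans_is_all_outside(self):
        s = AnnotatedSentence("abcde")
        assert bio_encode(s) == ("O",) * 5

    def test_single_span_encoding(self):
        s = AnnotatedSentence("abcde", (EntitySpan(1, 3, "Mass"),))
        assert bio_encode(s) == ("O", "B-Mass", "I-Mass", "O", "O")

    def test_overlapping_spans_error_names_pair(self):
        with pytest.raises(CorpusError, match="overlap"):
            AnnotatedSentence("abcde", (EntitySpan(0, 2, "Mass"), EntitySpan(1, 3, "Mass")))

    def test_one_b_and_rest_i_per_span(self):
        s = AnnotatedSentence(
            "abcdefgh", (EntitySpan(0, 3, "Mass"), EntitySpan(4, 6, "Lymph"))
        )
        tags = bio_encode(s)
        for span in s.spans:
            assert tags[span.start] == f"B-{span.type}"
            assert sum(t == f"I-{span.type}" for t in tags) >= span.length - 1

    def test_decode_inverts_encode(self):
        tags = ["O", "B-Mass", "I-Mass", "O"]
        assert bio_decode(tags) == (EntitySpan(1, 3, "Mass"),)

    def test_decode_repair_promotes_dangling_inside(self):
        assert bio_decode(["I-Mass", "O"], repair=True) == (EntitySpan(0, 1, "Mass"),)

    def test_decode_strict_rejects_dangling_inside(self):
        with pytest.raises(CorpusError, match="position 0"):
            bio_decode(["I-Mass", "O"])

    def test_decode_rejects_unknown_tag(self):
        with pytest.raises(CorpusError, match="unknown tag"):
            bio_decode(["X-Mass"])

    def test_adjacent_spans_separated_by_b_tag(self):
        tags = ["B-Mass", "B-Mass", "I-Mass"]
        assert bio_decode(tags) == (EntitySpan(0, 1, "Mass"), EntitySpan(1, 3, "Mass"))

    def test_round_trip_exhaustive_short_sentences(self):
        # every valid span configuration on sentences of length <= 4 over 2 types
        types = ("Mass", "Location")
        for n in range(1, 5):
            candidates = [
                EntitySpan(i, j, t)
                for i in range(n)
                for j in range(i + 1, n + 1)
                for t in types
            ]
            for r in range(0, 4):
                for combo in itertools.combinations(candidates, r):
                    try:
                        s = AnnotatedSentence("x" * n, combo)
                    except CorpusError:
                        continue
                    assert bio_decode(bio_encode(s)) == tuple(sorted(combo))

    def test_round_trip_random_generated_sentences(self):
        docs = generate_corpus(SynthConfig(n_documents=40, seed=3))
        checked = 0
        for doc in docs:
            for s in doc.sentences:
                assert bio_decode(bio_encode(s)) == s.spans
                checked += 1
        assert checked >= 200

    def test_label_alphabet_size(self):
        assert len(bio_label_alphabet()) == 1 + 2 * len(DEFAULT_REGISTRY)

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(1, 6), st.sampled_from(["Mass", "Lymph"])),
            max_size=6,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_property_on_arbitrary_span_layouts(self, raw):
        # lay candidate spans left to right, discarding overlaps
        spans, cursor = [], 0
        for gap, length, t in raw:
            start = cursor + gap
            spans.append(EntitySpan(start, start + length, t))
            cursor = start + length
        n = max(cursor, 1)
        s = AnnotatedSentence("x" * n, tuple(spans))
        assert bio_decode(bio_encode(s)) == tuple(sorted(spans))


class TestRegistry:
    def test_default_has_fourteen_types(self):
        assert len(DEFAULT_REGISTRY) == 14

    def test_duplicate_names_rejected(self):
        with pytest.raises(CorpusError):
            EntityTypeRegistry(["Mass", "Mass"])

    def test_extensible_by_config(self):
        reg = EntityTypeRegistry(["Drug", "Dose"])
        assert "Drug" in reg and len(reg) == 2


class TestConllFormat:
    def test_read_fixture_file(self):
        docs = read_conll(DATA / "sample.conll")
        assert len(docs) == 2
        sent = docs[0].sentences[0]
        assert sent.chars == "肺叶内见结节"
        assert sent.spans == (EntitySpan(0, 2, "Location"), EntitySpan(4, 6, "Mass"))

    def test_byte_exact_round_trip(self, tmp_path):
        raw = (DATA / "sample.conll").read_bytes()
        docs = read_conll(DATA / "sample.conll")
        out = tmp_path / "out.conll"
        write_conll(docs, out)
        assert out.read_bytes() == raw

    def test_corpus_round_trip(self, small_corpus, tmp_path):
        path = tmp_path / "c.conll"
        write_conll(small_corpus, path)
        back = read_conll(path)
        assert len(back) == len(small_corpus)
        for a, b in zip(small_corpus, back):
            assert a.id == b.id
            assert [s.chars for s in a.sentences] == [s.chars for s in b.sentences]
            assert [s.spans for s in a.sentences] == [s.spans for s in b.sentences]

    def test_empty_file_is_empty_corpus(self, tmp_path):
        p = tmp_path / "empty.conll"
        p.write_text("")
        assert read_conll(p) == []

    def test_single_column_line_is_parse_error_with_line_number(self, tmp_path):
        p = tmp_path / "bad.conll"
        p.write_text("-DOCSTART- d1\n肺\n")
        with pytest.raises(CorpusError, match="line 2"):
            read_conll(p)

    def test_unknown_tag_prefix_rejected(self, tmp_path):
        p = tmp_path / "bad.conll"
        p.write_text("-DOCSTART- d1\n肺\tQ-Mass\n")
        with pytest.raises(CorpusError, match="unknown tag prefix"):
            read_conll(p)


class TestStandoffFormat:
    def test_read_fixture_file(self):
        docs = read_standoff(DATA / "sample.jsonl")
        sent = docs[0].sentences[0]
        assert sent.chars == "左肺结节"
        assert sent.spans == (EntitySpan(2, 4, "Mass"),)
        assert bio_encode(sent) == ("O", "O", "B-Mass", "I-Mass")

    def test_span_outside_text_bounds_rejected(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text(
            '{"doc_id": "d", "text": "左肺结节", "spans": [["Mass", 3, 7]]}\n',
            encoding="utf-8",
        )
        with pytest.raises(CorpusError, match="exceeds"):
            read_standoff(p)

    def test_round_trip_lossless_on_generated_documents(self, tmp_path):
        docs = generate_corpus(SynthConfig(n_documents=100, seed=11))
        path = tmp_path / "c.jsonl"
        write_standoff(docs, path)
        back = read_standoff(path)
        assert [d.id for d in back] == [d.id for d in docs]
        for a, b in zip(docs, back):
            assert [s.chars for s in a.sentences] == [s.chars for s in b.sentences]
            assert [s.spans for s in a.sentences] == [s.spans for s in b.sentences]
            assert a.split_role == b.split_role


class TestStatisticsAndHelpers:
    def test_single_span_statistics(self):
        doc = Document("d", [AnnotatedSentence("abcd", (EntitySpan(1, 3, "Mass"),))])
        stats = corpus_statistics([doc])
        row = stats[stats.entity_type == "Mass"].iloc[0]
        assert row["count"] == 1 and row["mean_length"] == 2

    def test_mean_length_over_two_spans(self):
        doc = Document(
            "d",
            [
                AnnotatedSentence("abcdef", (EntitySpan(0, 2, "Mass"),)),
                AnnotatedSentence("abcdef", (EntitySpan(0, 4, "Mass"),)),
            ],
        )
        stats = corpus_statistics([doc])
        assert stats[stats.entity_type == "Mass"].iloc[0]["mean_length"] == 3.0

    def test_zero_span_types_omitted(self):
        doc = Document("d", [AnnotatedSentence("ab")])
        assert corpus_statistics([doc]).empty

    def test_sentence_splitter_keeps_delimiters(self):
        parts = split_sentences("双肺纹理清。未见异常；")
        assert parts == ["双肺纹理清。", "未见异常；"]

    def test_duplicate_document_ids_rejected(self, tmp_path):
        docs = [Document("d", [AnnotatedSentence("ab")]), Document("d", [AnnotatedSentence("cd")])]
        with pytest.raises(CorpusError, match="unique"):
            write_conll(docs, tmp_path / "x.conll")
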