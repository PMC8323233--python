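"""Data model for character-level NER corpora.

Documents hold sentences of characters annotated with typed, non-overlapping
entity spans.  Spans use 0-based half-open character offsets, matching the
BIO tag indexing one-to-one (the tagger is character-level; no word
segmentation is performed).  Two on-disk dialects are supported: a
two-column CoNLL-style character/tag format and a line-delimited JSON
standoff format (text + typed span triples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: The default clinical entity schema: 14 categories covering lung-cancer
#: screening and staging information in chest CT findings.
DEFAULT_ENTITY_TYPES = (
    "Vessel",
    "VertebralBody",
    "PAOP",
    "Bronchus",
    "Pleura",
    "Shape",
    "Density",
    "Mass",
    "Enhancement",
    "Size",
    "Location",
    "Lymph",
    "Negation",
    "Effusion",
)

SPLIT_ROLES = ("train", "validation", "test", "unlabeled")


class CorpusError(ValueError):
    """Raised on invalid annotations or malformed corpus files."""


class EntityTypeRegistry:
    """Ordered registry of entity type names; extensible by configuration."""

    def __init__(self, names: Sequence[str] = DEFAULT_ENTITY_TYPES):
        names = list(names)
        if len(set(names)) != len(names):
            raise CorpusError("entity type names must be unique")
        self.names = tuple(names)
        self._index = {n: i for i, n in enumerate(names)}

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __iter__(self):
        return iter(self.names)

    def __len__(self):
        return len(self.names)

    def index(self, name: str) -> int:
        return self._index[name]


DEFAULT_REGISTRY = EntityTypeRegistry()


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed, half-open character interval ``[start, end)``."""

    start: int
    end: int
    type: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


def validate_spans(spans: Iterable[EntitySpan], n_chars: int | None = None) -> list[EntitySpan]:
    """Sort spans, check bounds and reject overlaps (names the offending pair)."""
    spans = sorted(spans)
    for a, b in zip(spans, spans[1:]):
        if a.overlaps(b):
            raise CorpusError(f"overlapping spans: {a} and {b}")
    if n_chars is not None:
        for s in spans:
            if s.end > n_chars:
                raise CorpusError(f"span {s} exceeds sentence length {n_chars}")
    return spans


@dataclass
class AnnotatedSentence:
    """A character sequence with gold entity spans and/or BIO tags."""

    chars: str
    spans: tuple[EntitySpan, ...] = ()
    tags: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(self.chars) < 1:
            raise CorpusError("sentence must contain at least one character")
        self.spans = tuple(validate_spans(self.spans, len(self.chars)))
        if self.tags is not None:
            self.tags = tuple(self.tags)
            if len(self.tags) != len(self.chars):
                raise CorpusError("tag sequence length must equal character count")

    def __len__(self) -> int:
        return len(self.chars)

    def with_tags(self) -> "AnnotatedSentence":
        return replace(self, tags=bio_encode(self))


@dataclass
class Document:
    id: str
    sentences: list[AnnotatedSentence] = field(default_factory=list)
    split_role: str = "unlabeled"

    def __post_init__(self):
        if self.split_role not in SPLIT_ROLES:
            raise CorpusError(f"unknown split_role {self.split_role!r}")

    @property
    def text(self) -> str:
        return "".join(s.chars for s in self.sentences)


def check_unique_ids(docs: Sequence[Document]) -> None:
    ids = [d.id for d in docs]
    if len(set(ids)) != len(ids):
        raise CorpusError("document ids must be unique within a corpus")


# ---------------------------------------------------------------------------
# BIO encoding
# ---------------------------------------------------------------------------

def bio_encode(sentence: AnnotatedSentence) -> tuple[str, ...]:
    """Encode gold spans as BIO tags: B-T at span starts, I-T inside, O elsewhere."""
    tags = ["O"] * len(sentence)
    for span in validate_spans(sentence.spans, len(sentence)):
        tags[span.start] = f"B-{span.type}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.type}"
    return tuple(tags)


def bio_decode(tags: Sequence[str], repair: bool = False) -> tuple[EntitySpan, ...]:
    """Recover entity spans from a BIO tag sequence.

    With ``repair`` off this is the exact inverse of :func:`bio_encode` and
    raises on invalid sequences (an ``I-T`` with no adjacent same-type
    predecessor).  With ``repair`` on, such a dangling ``I-T`` opens a new
    span, as if it were ``B-T`` — appropriate for model predictions from
    taggers without transition constraints.
    """
    spans: list[EntitySpan] = []
    open_start, open_type = None, None

    def close():
        nonlocal open_start, open_type
        if open_start is not None:
            spans.append(EntitySpan(open_start, i_close, open_type))
            open_start, open_type = None, None

    for i, tag in enumerate(tags):
        i_close = i
        if tag == "O":
            close()
        elif tag.startswith("B-"):
            close()
            open_start, open_type = i, tag[2:]
        elif tag.startswith("I-"):
            t = tag[2:]
            if open_type == t:
                continue
            if not repair:
                raise CorpusError(f"invalid BIO sequence at position {i}: {tag}")
            close()
            open_start, open_type = i, t
        else:
            raise CorpusError(f"unknown tag {tag!r} at position {i}")
    i_close = len(tags)
    close()
    return tuple(spans)


def bio_label_alphabet(registry: EntityTypeRegistry = DEFAULT_REGISTRY) -> tuple[str, ...]:
    """Ordered label set: O first, then B-T/I-T per registry order."""
    labels = ["O"]
    for name in registry:
        labels.extend([f"B-{name}", f"I-{name}"])
    return tuple(labels)


# ---------------------------------------------------------------------------
# CoNLL-style two-column format
# ---------------------------------------------------------------------------

DOCSTART = "-DOCSTART-"


def write_conll(docs: Sequence[Document], path) -> None:
    check_unique_ids(docs)
    lines: list[str] = []
    for doc in docs:
        lines.append(f"{DOCSTART} {doc.id} {doc.split_role}")
        for sent in doc.sentences:
            tags = sent.tags if sent.tags is not None else bio_encode(sent)
            for ch, tag in zip(sent.chars, tags):
                lines.append(f"{ch}\t{tag}")
            lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_conll(path, repair: bool = False) -> list[Document]:
    docs: list[Document] = []
    cur_doc: Document | None = None
    chars: list[str] = []
    tags: list[str] = []

    def flush_sentence(lineno):
        nonlocal chars, tags
        if not chars:
            return
        if cur_doc is None:
            raise CorpusError(f"line {lineno}: sentence before any {DOCSTART} header")
        sent = AnnotatedSentence(
            "".join(chars), bio_decode(tags, repair=repair), tuple(tags)
        )
        cur_doc.sentences.append(sent)
        chars, tags = [], []

    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.split("\n"), start=1):
        line = line.rstrip("\n")
        if line.startswith(DOCSTART):
            flush_sentence(lineno)
            parts = line.split()
            doc_id = parts[1] if len(parts) > 1 else f"doc{len(docs)}"
            role = parts[2] if len(parts) > 2 else "unlabeled"
            cur_doc = Document(doc_id, [], role)
            docs.append(cur_doc)
        elif line.strip() == "":
            flush_sentence(lineno)
        else:
            cols = line.split("\t")
            if len(cols) != 2 or len(cols[0]) != 1:
                raise CorpusError(f"parse error at line {lineno}: {line!r}")
            ch, tag = cols
            if tag != "O" and not (tag.startswith("B-") or tag.startswith("I-")):
                raise CorpusError(f"unknown tag prefix at line {lineno}: {tag!r}")
            chars.append(ch)
            tags.append(tag)
    flush_sentence(lineno)
    check_unique_ids(docs)
    return docs


# ---------------------------------------------------------------------------
# Line-delimited JSON standoff format
# ---------------------------------------------------------------------------

def write_standoff(docs: Sequence[Document], path) -> None:
    check_unique_ids(docs)
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            for i, sent in enumerate(doc.sentences):
                record = {
                    "doc_id": doc.id,
                    "split_role": doc.split_role,
                    "sentence_index": i,
                    "text": sent.chars,
                    "spans": [[s.type, s.start, s.end] for s in sent.spans],
                }
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_standoff(path) -> list[Document]:
    docs: dict[str, Document] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"parse error at line {lineno}: {exc}") from exc
            spans = [EntitySpan(int(s), int(e), t) for t, s, e in rec["spans"]]
            try:
                sent = AnnotatedSentence(rec["text"], tuple(spans))
            except CorpusError as exc:
                raise CorpusError(f"line {lineno}: {exc}") from exc
            doc = docs.setdefault(
                rec["doc_id"],
                Document(rec["doc_id"], [], rec.get("split_role", "unlabeled")),
            )
            doc.sentences.append(sent)
    return list(docs.values())


# ---------------------------------------------------------------------------
# Statistics and helpers
# ---------------------------------------------------------------------------

def corpus_statistics(docs: Sequence[Document]) -> pd.DataFrame:
    """Per-type span count and mean character length, as a DataFrame.

    Types with zero spans are omitted (their mean length is undefined).
    """
    rows: dict[str, list[int]] = {}
    for doc in docs:
        for sent in doc.sentences:
            for span in sent.spans:
                rows.setdefault(span.type, []).append(span.length)
    out = pd.DataFrame(
        {
            "entity_type": list(rows),
            "count": [len(v) for v in rows.values()],
            "mean_length": [sum(v) / len(v) for v in rows.values()],
        }
    ).sort_values("count", ascending=False, ignore_index=True)
    return out


SENTENCE_DELIMITERS = "。；!?！？"


def split_sentences(text: str) -> list[str]:
    """Split raw report text on 。；!? delimiters (keeping the delimiter).

    Heuristic helper only — how findings were segmented into model input
    sequences is a corpus-preparation choice, not a property of the model.
    """
    out, buf = [], []
    for ch in text:
        buf.append(ch)
        if ch in SENTENCE_DELIMITERS:
            out.append("".join(buf))
            buf = []
    if buf:
        out.append("".join(buf))
    return [s for s in out if s.strip()]
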