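"""Seeded generator of synthetic CT-report-like annotated corpora.

The generator emulates the *statistical* structure of an annotated chest-CT
findings corpus — relative entity-type frequencies, per-type span-length
distributions, clause ordering, negation, and optional cross-type lexical
ambiguity — without attempting clinically plausible prose.  Characters are
drawn from disjoint CJK codepoint blocks: one background lexicon plus one
sublexicon per entity type, so that with default settings the task is
learnable nearly perfectly; an ambiguity knob shares surface forms between
confusable types (e.g. pleural vs. bronchial invasion descriptions) to make
typing context-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    DEFAULT_ENTITY_TYPES,
    AnnotatedSentence,
    CorpusError,
    Document,
    EntitySpan,
)

#: Default per-type relative frequencies and mean span lengths (characters).
#: They mirror the makeup of a real annotated chest-CT corpus: location and
#: negation mentions dominate; vessel and vertebral-body invasion mentions
#: are rare but long.
DEFAULT_TYPE_FREQUENCIES = {
    "Vessel": 51,
    "VertebralBody": 28,
    "PAOP": 85,
    "Bronchus": 58,
    "Pleura": 230,
    "Shape": 513,
    "Density": 340,
    "Mass": 874,
    "Enhancement": 185,
    "Size": 774,
    "Location": 1937,
    "Lymph": 588,
    "Negation": 924,
    "Effusion": 412,
}

DEFAULT_MEAN_LENGTHS = {
    "Vessel": 10.82,
    "VertebralBody": 13.75,
    "PAOP": 8.77,
    "Bronchus": 4.66,
    "Pleura": 4.27,
    "Shape": 4.37,
    "Density": 5.00,
    "Mass": 4.11,
    "Enhancement": 5.44,
    "Size": 7.35,
    "Location": 8.77,
    "Lymph": 4.66,
    "Negation": 4.27,
    "Effusion": 4.37,
}

#: Canonical clause order within a sentence: negation first, then the
#: location -> mass -> attribute chain, lymph, invasion clauses, effusion.
CLAUSE_ORDER = (
    "Negation",
    "Location",
    "Mass",
    "Shape",
    "Density",
    "Size",
    "Enhancement",
    "Lymph",
    "Vessel",
    "Pleura",
    "Bronchus",
    "VertebralBody",
    "PAOP",
    "Effusion",
)

#: Type pairs whose sublexicons are blended by the ambiguity knob
#: (surface forms that legitimately occur under either type).
AMBIGUOUS_PAIRS = (("Pleura", "Bronchus"), ("Mass", "Lymph"))

_SUBLEX_SIZE = 12
_BACKGROUND_SIZE = 40
_CJK_BASE = 0x4E00


def _default_lengths() -> dict:
    return {t: (DEFAULT_MEAN_LENGTHS[t], 4.0) for t in DEFAULT_ENTITY_TYPES}


@dataclass
class SynthConfig:
    """Configuration of the synthetic corpus generator.

    ``type_frequencies`` are relative weights (any nonnegative scale);
    ``length_distributions`` maps each type to ``(mean, dispersion)`` of a
    shifted negative-binomial span-length law (support >= 1), so that long
    types keep a heavy tail.  ``ambiguity`` in [0, 1] is the fraction of
    confusable-pair sublexicons drawn from a shared pool.  ``negation_rate``
    inserts *additional* negation tokens before negatable clauses, on top
    of the negation mentions already produced by the type frequencies.
    """

    n_documents: int = 359
    sentences_per_document: tuple[int, int] = (4, 8)
    entities_per_sentence: tuple[int, int] = (1, 5)
    type_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_FREQUENCIES))
    length_distributions: dict = field(default_factory=_default_lengths)
    ambiguity: float = 0.0
    negation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(w < 0 for w in self.type_frequencies.values()):
            raise CorpusError("type frequencies must be nonnegative")
        if not any(w > 0 for w in self.type_frequencies.values()):
            raise CorpusError("at least one type frequency must be positive")
        if any(m < 1 for m, _ in self.length_distributions.values()):
            raise CorpusError("span length means must be >= 1")
        if not 0.0 <= self.ambiguity <= 1.0:
            raise CorpusError("ambiguity must lie in [0, 1]")


def build_lexicons(config: SynthConfig) -> tuple[str, dict[str, str]]:
    """Background lexicon and per-type sublexicons as character strings."""
    background = "".join(chr(_CJK_BASE + i) for i in range(_BACKGROUND_SIZE))
    sublex = {}
    types = list(config.type_frequencies)
    for i, t in enumerate(types):
        base = _CJK_BASE + 0x100 + i * 0x20
        sublex[t] = "".join(chr(base + j) for j in range(_SUBLEX_SIZE))
    if config.ambiguity > 0:
        n_shared = max(1, int(round(config.ambiguity * _SUBLEX_SIZE)))
        for k, (a, b) in enumerate(AMBIGUOUS_PAIRS):
            if a not in sublex or b not in sublex:
                continue
            base = _CJK_BASE + 0x1000 + k * 0x20
            shared = "".join(chr(base + j) for j in range(n_shared))
            sublex[a] = shared + sublex[a][n_shared:]
            sublex[b] = shared + sublex[b][n_shared:]
    return background, sublex


def _sample_length(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Shifted negative binomial: 1 + NB(r, p) with mean `mean`."""
    if mean <= 1.0:
        return 1
    r = dispersion
    p = r / (r + (mean - 1.0))
    return 1 + int(rng.negative_binomial(r, p))


def _clause_rank(t: str) -> int:
    try:
        return CLAUSE_ORDER.index(t)
    except ValueError:
        return len(CLAUSE_ORDER)


def generate_corpus(config: SynthConfig) -> list[Document]:
    """Generate a seeded annotated corpus with exactly recorded gold spans."""
    rng = np.random.default_rng(config.seed)
    background, sublex = build_lexicons(config)
    types = [t for t, w in config.type_frequencies.items() if w > 0]
    weights = np.array([config.type_frequencies[t] for t in types], dtype=float)
    weights /= weights.sum()
    negatable = {"Mass", "Lymph", "Effusion"}

    docs: list[Document] = []
    for d in range(config.n_documents):
        lo, hi = config.sentences_per_document
        n_sent = int(rng.integers(lo, hi + 1))
        sentences = []
        for _ in range(n_sent):
            e_lo, e_hi = config.entities_per_sentence
            k = int(rng.integers(e_lo, e_hi + 1))
            chosen = list(rng.choice(len(types), size=k, p=weights))
            ents = sorted((types[i] for i in chosen), key=_clause_rank)
            if (
                config.negation_rate > 0
                and any(t in negatable for t in ents)
                and rng.random() < config.negation_rate
            ):
                ents.insert(0, "Negation")
            chars: list[str] = []
            spans: list[EntitySpan] = []

            def filler(n):
                idx = rng.integers(0, len(background), size=n)
                chars.extend(background[j] for j in idx)

            filler(int(rng.integers(1, 3)))
            for t in ents:
                mean, disp = config.length_distributions.get(t, (4.0, 4.0))
                length = _sample_length(rng, mean, disp)
                lex = sublex[t]
                start = len(chars)
                idx = rng.integers(0, len(lex), size=length)
                chars.extend(lex[j] for j in idx)
                spans.append(EntitySpan(start, start + length, t))
                filler(int(rng.integers(1, 4)))
            chars.append("。")  # sentence-final period
            sentences.append(AnnotatedSentence("".join(chars), tuple(spans)).with_tags())
        docs.append(Document(f"synth-{config.seed}-{d:04d}", sentences))
    return docs


def perturb_labels(
    docs: list[Document],
    noise_rate: float,
    seed: int,
    operations: tuple[str, ...] = ("shift", "retype", "drop"),
    type_names: tuple[str, ...] = DEFAULT_ENTITY_TYPES,
) -> list[Document]:
    """Corrupt gold spans to build prediction sets with known agreement.

    Each span independently, with probability ``noise_rate``, undergoes one
    of the allowed operations (uniform choice): ``shift`` moves the span by
    one character (only spans of length >= 2, so the shifted span still
    overlaps the original and same-type inexact recall stays 1.0 under
    shift-only noise), ``retype`` assigns a different type, ``drop`` removes
    the span.  A shift that would collide with a neighbouring span or the
    sentence bounds falls back to the opposite direction, then to identity.
    """
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out_docs = []
    for doc in docs:
        new_sents = []
        for sent in doc.sentences:
            kept: list[EntitySpan] = []
            for span in sent.spans:
                if rng.random() >= noise_rate:
                    kept.append(span)
                    continue
                op = operations[int(rng.integers(0, len(operations)))]
                if op == "drop":
                    continue
                if op == "retype":
                    others = [t for t in type_names if t != span.type]
                    new_t = others[int(rng.integers(0, len(others)))]
                    kept.append(EntitySpan(span.start, span.end, new_t))
                    continue
                # shift
                if span.length < 2:
                    kept.append(span)
                    continue
                delta = 1 if rng.random() < 0.5 else -1
                placed = span
                for dd in (delta, -delta):
                    cand_s, cand_e = span.start + dd, span.end + dd
                    if cand_s < 0 or cand_e > len(sent.chars):
                        continue
                    cand = EntitySpan(cand_s, cand_e, span.type)
                    others = kept + [s for s in sent.spans if s != span]
                    if any(cand.overlaps(o) for o in others):
                        continue
                    placed = cand
                    break
                kept.append(placed)
            new_sents.append(AnnotatedSentence(sent.chars, tuple(sorted(kept))))
        out_docs.append(Document(doc.id, new_sents, doc.split_role))
    return out_docs
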