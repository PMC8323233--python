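import numpy as np
import pytest

from btner.corpus import AnnotatedSentence, Document, EntitySpan
from btner.embeddings import EmbeddingMatrix, LookupProvider, Vocabulary
from btner.network import BtnModel, ModelConfig
from btner.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic corpus (30 documents)."""
    return generate_corpus(SynthConfig(n_documents=30, seed=7))


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return Vocabulary.from_documents(small_corpus)


@pytest.fixture
def tiny_model_factory(small_corpus, small_vocab):
    """Build a deliberately small tagger for fast structural tests."""

    def build(variant="btn", dropout=0.0, seed=0, **kwargs):
        cfg = ModelConfig(
            embedding_dim=8,
            lstm_hidden_size=6,
            transformer_dim=kwargs.pop("transformer_dim", 12),
            feedforward_dim=kwargs.pop("feedforward_dim", 16),
            dropout=dropout,
            variant=variant,
            **kwargs,
        )
        matrix = EmbeddingMatrix.random(small_vocab, 8, seed=seed)
        return BtnModel(LookupProvider(small_vocab, matrix), cfg, seed=seed)

    return build


@pytest.fixture
def hand_sentence():
    """5 characters with a single 2-char mass span at [1, 3)."""
    return AnnotatedSentence("肺内结节影", (EntitySpan(1, 3, "Mass"),))


def random_sentence(rng, n_types=2, max_len=8):
    """A random valid annotated sentence over a reduced type alphabet."""
    types = ["Mass", "Location", "Pleura"][:n_types]
    n = int(rng.integers(1, max_len + 1))
    spans, pos = [], 0
    while pos < n:
        if rng.random() < 0.5:
            length = int(rng.integers(1, min(3, n - pos) + 1))
            spans.append(EntitySpan(pos, pos + length, types[int(rng.integers(n_types))]))
            pos += length
        pos += int(rng.integers(0, 3))
    chars = "字" * n
    return AnnotatedSentence(chars, tuple(s for s in spans if s.end <= n))
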