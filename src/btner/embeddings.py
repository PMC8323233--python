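"""Character-embedding providers.

The tagger treats its embedding layer as a pluggable provider: anything
mapping a character sequence to a sequence of D-dimensional vectors.  The
reference provider is a static lookup table (the FastText-style baseline
family); contextual providers — e.g. a masked-language-model encoder — plug
in through :func:`contextual_adapter`, and a small self-attention
"mini contextual" provider ships for tests so the contextual pathway is
exercised without any pretrained weights or downloads.

Providers are frozen by default: the tagger never fine-tunes its embedding
layer, mirroring the pre-training stage's freezing of everything outside
the trunk.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from .autograd import Parameter

PAD, UNK = "<PAD>", "<UNK>"


class Vocabulary:
    """Dense character-to-index map with reserved PAD (index 0) and UNK."""

    def __init__(self, chars: Iterable[str]):
        inventory = []
        seen = set()
        for ch in chars:
            if ch not in seen:
                seen.add(ch)
                inventory.append(ch)
        self.itos = [PAD, UNK] + inventory
        self.stoi = {ch: i for i, ch in enumerate(self.itos)}

    def __len__(self):
        return len(self.itos)

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def unk_index(self) -> int:
        return 1

    def encode(self, chars: Sequence[str]) -> np.ndarray:
        return np.array([self.stoi.get(ch, self.unk_index) for ch in chars], dtype=np.int64)

    @classmethod
    def from_documents(cls, docs) -> "Vocabulary":
        return cls(ch for doc in docs for sent in doc.sentences for ch in sent.chars)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for ch in self.itos[2:]:
                fh.write(ch + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls(line.rstrip("\n") for line in fh if line.rstrip("\n"))


class EmbeddingMatrix:
    """Per-character vector table; row count equals vocabulary size."""

    def __init__(self, table: np.ndarray, trainable: bool = False):
        table = np.asarray(table, dtype=np.float64)
        if table.ndim != 2:
            raise ValueError("embedding table must be 2-D")
        self.param = Parameter(table, name="embedding", frozen=not trainable)

    @property
    def data(self) -> np.ndarray:
        return self.param.data

    @property
    def dim(self) -> int:
        return self.param.data.shape[1]

    @classmethod
    def random(cls, vocab: Vocabulary, dim: int, seed: int, trainable: bool = False):
        rng = np.random.default_rng(seed)
        table = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(len(vocab), dim))
        table[vocab.pad_index] = 0.0  # PAD embeds to the zero row
        return cls(table, trainable=trainable)


def lookup_embed(vocab: Vocabulary, matrix: EmbeddingMatrix, chars: Sequence[str]) -> np.ndarray:
    """Static table lookup with UNK fallback; PAD positions map to zeros."""
    if matrix.data.shape[0] != len(vocab):
        raise ValueError(
            f"embedding rows ({matrix.data.shape[0]}) != vocabulary size ({len(vocab)})"
        )
    return matrix.data[vocab.encode(chars)]


class LookupProvider:
    """The static (FastText-analogue) embedding provider.

    Trainable by default, as is standard for a lookup embedding layer in
    supervised tagging; the pre-training stage freezes it regardless of
    this flag.  Set ``frozen=True`` for a fixed feature table.
    """

    def __init__(self, vocab: Vocabulary, matrix: EmbeddingMatrix, frozen: bool = False):
        self.vocab = vocab
        self.matrix = matrix
        self.frozen = frozen
        matrix.param.frozen = frozen

    @property
    def dim(self) -> int:
        return self.matrix.dim

    def embed(self, chars: Sequence[str]) -> np.ndarray:
        return lookup_embed(self.vocab, self.matrix, chars)

    def static_table(self) -> EmbeddingMatrix:
        return self.matrix

    def parameters(self):
        return [self.matrix.param]


class ContextualAdapter:
    """Wrap an external char-sequence -> vector-sequence callable as a provider.

    Results are cached per sentence; contextual providers expose no static
    table, so pre-training targets fall back to per-occurrence vectors.
    """

    def __init__(self, fn: Callable[[Sequence[str]], np.ndarray], dim: int, frozen: bool = True):
        self.fn = fn
        self.dim = dim
        self.frozen = frozen
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, chars: Sequence[str]) -> np.ndarray:
        key = "".join(chars)
        if key in self._cache:
            return self._cache[key]
        out = np.asarray(self.fn(chars), dtype=np.float64)
        if out.shape != (len(chars), self.dim):
            raise ValueError(
                f"provider returned shape {out.shape}, expected {(len(chars), self.dim)}"
            )
        self._cache[key] = out
        return out

    def static_table(self):
        return None

    def parameters(self):
        return []


def contextual_adapter(fn, dim: int, frozen: bool = True) -> ContextualAdapter:
    return ContextualAdapter(fn, dim, frozen=frozen)


class MiniContextualProvider(ContextualAdapter):
    """A tiny fixed-weight 2-layer self-attention encoder for tests.

    Gives the same character different vectors in different contexts,
    exercising the contextual-provider contract without pretrained weights.
    """

    def __init__(self, vocab: Vocabulary, dim: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        table = rng.normal(0, 1 / np.sqrt(dim), size=(len(vocab), dim))
        table[vocab.pad_index] = 0.0
        Ws = [rng.normal(0, 1 / np.sqrt(dim), size=(dim, dim)) for _ in range(6)]

        def fn(chars):
            x = table[vocab.encode(chars)]
            for layer in range(2):
                q, k, v = (x @ Ws[3 * layer + j] for j in range(3))
                att = q @ k.T / np.sqrt(dim)
                att = np.exp(att - att.max(axis=-1, keepdims=True))
                att /= att.sum(axis=-1, keepdims=True)
                x = x + att @ v
            return x

        super().__init__(fn, dim, frozen=True)
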