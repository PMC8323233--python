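"""Unsupervised pre-training on TF-IDF-weighted character embeddings.

The idea: before any labels are seen, teach the trunk (BiLSTM, Transformer
layer and a linear head) to regress, for each character of a report, onto
that character's embedding scaled by its normalized TF-IDF weight in the
report.  Characters that are distinctive for a report get large targets;
boilerplate shared by every report gets weight 0.  The regression head is a
tanh layer that replaces the CRF during this stage, trained with MSE; the
embedding provider and the CRF are frozen, and only the trunk transfers to
supervised tagging.

TF-IDF is computed over characters, with one document per report, as

    TFIDF(w, d) = TF(w, d) * log(N / DF(w))

(natural log; the base is immaterial because a global min-max normalization
to [0, 1] follows).  The corpus must exclude test-split documents — a guard
enforces it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autograd import Adam, Tensor, stack
from .corpus import CorpusError, Document
from .network import BtnModel

#: Components updated during pre-training; everything else is frozen.
TRAINABLE_COMPONENTS = ("bilstm", "transformer", "projection", "pretrain_head")


@dataclass
class TfidfTable:
    """Raw counts and TF-IDF weights over (character, document) pairs."""

    tf: dict = field(default_factory=dict)          # (w, d) -> count
    df: dict = field(default_factory=dict)          # w -> number of docs containing w
    n_documents: int = 0
    tfidf: dict = field(default_factory=dict)       # (w, d) -> weight
    tfidf_normalized: dict = field(default_factory=dict)

    def weight(self, char: str, doc_id: str) -> float:
        """Normalized weight; characters unseen in the table get 0."""
        return self.tfidf_normalized.get((char, doc_id), 0.0)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("token\tdocument\ttf\ttfidf\ttfidf_normalized\n")
            for (w, d), v in sorted(self.tfidf.items(), key=lambda kv: (kv[0][1], kv[0][0])):
                fh.write(
                    f"{w}\t{d}\t{self.tf[(w, d)]}\t{v:.10g}\t"
                    f"{self.tfidf_normalized.get((w, d), float('nan')):.10g}\n"
                )


def guard_no_test_documents(docs: Sequence[Document]) -> None:
    bad = [d.id for d in docs if d.split_role == "test"]
    if bad:
        raise CorpusError(
            f"test-split documents must not enter the pre-training corpus: {bad[:5]}"
        )


def compute_tfidf(docs: Sequence[Document]) -> TfidfTable:
    """Character-level TF-IDF with natural log; keys only for observed pairs."""
    docs = list(docs)
    if not docs:
        raise CorpusError("TF-IDF needs at least one document")
    guard_no_test_documents(docs)
    table = TfidfTable(n_documents=len(docs))
    for doc in docs:
        seen = set()
        for ch in doc.text:
            table.tf[(ch, doc.id)] = table.tf.get((ch, doc.id), 0) + 1
            seen.add(ch)
        for ch in seen:
            table.df[ch] = table.df.get(ch, 0) + 1
    N = table.n_documents
    for (w, d), tf in table.tf.items():
        table.tfidf[(w, d)] = tf * math.log(N / table.df[w])
    return table


def normalize_tfidf(table: TfidfTable, scope: str = "global") -> TfidfTable:
    """Min-max normalization of TF-IDF weights to [0, 1].

    ``scope="global"`` (default) takes one min-max over all stored (w, d)
    values; ``scope="per_document"`` rescales within each document.  When
    max equals min over a scope, its normalized values are all 0.
    """
    if not table.tfidf:
        raise CorpusError("TF-IDF table is empty; call compute_tfidf first")

    def minmax(items):
        vals = [v for _, v in items]
        lo, hi = min(vals), max(vals)
        if hi == lo:
            return {k: 0.0 for k, _ in items}
        return {k: (v - lo) / (hi - lo) for k, v in items}

    if scope == "global":
        table.tfidf_normalized = minmax(list(table.tfidf.items()))
    elif scope == "per_document":
        by_doc: dict = {}
        for (w, d), v in table.tfidf.items():
            by_doc.setdefault(d, []).append(((w, d), v))
        table.tfidf_normalized = {}
        for items in by_doc.values():
            table.tfidf_normalized.update(minmax(items))
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    return table


def build_targets(table: TfidfTable, provider, sentence, doc_id: str) -> np.ndarray:
    """Per-character regression targets: weight(char, doc) times its embedding."""
    E = provider.embed(sentence.chars)
    if E.shape[0] != len(sentence):
        raise ValueError("provider output length mismatch")
    w = np.array([table.weight(ch, doc_id) for ch in sentence.chars])
    return w[:, None] * E


def pretrain_loss(y_hat: np.ndarray | Tensor, y_star: np.ndarray) -> float | Tensor:
    """MSE over the sentence: mean over tokens of the squared L2 distance."""
    data = y_hat.data if isinstance(y_hat, Tensor) else np.asarray(y_hat)
    y_star = np.asarray(y_star)
    if data.shape != y_star.shape:
        raise ValueError(f"shape mismatch: {data.shape} vs {y_star.shape}")
    if isinstance(y_hat, Tensor):
        return ((y_hat - Tensor(y_star)) ** 2).sum(axis=-1).mean()
    return float(((data - y_star) ** 2).sum(axis=-1).mean())


@dataclass
class PretrainRecord:
    epoch_losses: list[float] = field(default_factory=list)
    checksums_before: dict = field(default_factory=dict)
    checksums_after: dict = field(default_factory=dict)


def run_pretraining(
    model: BtnModel,
    docs: Sequence[Document],
    epochs: int = 5,
    lr: float = 1e-4,
    batch_size: int = 32,
    seed: int = 0,
    table: TfidfTable | None = None,
) -> tuple[dict, PretrainRecord]:
    """Minimize the TF-IDF regression objective with Adam.

    Only the trunk and the tanh head are updated; the embedding provider
    and the CRF are frozen (checksummed in the returned record).  Returns
    the model state dict (the warm-start checkpoint) and a training record
    with per-epoch mean losses.
    """
    docs = list(docs)
    guard_no_test_documents(docs)
    if table is None:
        table = normalize_tfidf(compute_tfidf(docs))

    model.set_mode("pretrain")
    frozen = [c for c in model.components() if c not in TRAINABLE_COMPONENTS]
    record = PretrainRecord(checksums_before=model.component_checksums())

    items = [
        (sent, build_targets(table, model.provider, sent, doc.id))
        for doc in docs
        for sent in doc.sentences
    ]
    from .training import _length_bucketed_batches

    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    for _ in range(epochs):
        batches = _length_bucketed_batches(
            items, batch_size, rng, key=lambda it: len(it[0])
        )
        losses = []
        for batch in batches:
            sents = [s for s, _ in batch]
            y_hat, mask = model.pretrain_outputs(sents, training=True)
            per_sentence = []
            for b, (s, target) in enumerate(batch):
                per_sentence.append(pretrain_loss(y_hat[b, : len(s), :], target))
            loss = stack(per_sentence).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        record.epoch_losses.append(float(np.mean(losses)))
    record.checksums_after = model.component_checksums()
    for comp in frozen:
        if record.checksums_before[comp] != record.checksums_after[comp]:
            raise AssertionError(f"frozen component {comp!r} changed during pre-training")
    return model.state_dict(), record
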