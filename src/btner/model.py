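"""High-level modelling interface: a tagger model object whose ``fit``
returns a results object with estimates, diagnostics and a summary table.

This is the recommended entry point for interactive use; the submodules it
wires together (:mod:`btner.network`, :mod:`btner.training`,
:mod:`btner.pretraining`, :mod:`btner.evaluation`) remain available for
finer control and for the command-line tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .corpus import Document, bio_label_alphabet
from .embeddings import EmbeddingMatrix, LookupProvider, Vocabulary
from .evaluation import EvalReport
from .network import BtnModel, ModelConfig
from .pretraining import compute_tfidf, normalize_tfidf, run_pretraining
from .training import RunRecord, TrainConfig, evaluate_on, train_ner


class BTNTagger:
    """A character-level clinical NER model bound to a split corpus.

    Parameters
    ----------
    train_docs, val_docs : lists of Document
        Annotated documents with ``split_role`` "train" / "validation".
    model_config : ModelConfig, optional
        Network hyperparameters (variant, widths, dropout, ...).
    embedding_dim : int
        Width of the static character-embedding table built from the
        training vocabulary (ignored when ``provider`` is given).
    provider : embedding provider, optional
        Any object with ``embed``/``static_table``/``parameters``;
        defaults to a frozen random lookup table over the corpus
        vocabulary.
    """

    def __init__(
        self,
        train_docs: list[Document],
        val_docs: list[Document],
        model_config: ModelConfig | None = None,
        embedding_dim: int = 64,
        provider=None,
        seed: int = 0,
    ):
        self.train_docs = train_docs
        self.val_docs = val_docs
        self.seed = seed
        self.config = model_config or ModelConfig(embedding_dim=embedding_dim)
        if provider is None:
            vocab = Vocabulary.from_documents(train_docs + val_docs)
            matrix = EmbeddingMatrix.random(vocab, embedding_dim, seed=seed)
            provider = LookupProvider(vocab, matrix, frozen=True)
        self.provider = provider
        self.labels = bio_label_alphabet()
        self.network = BtnModel(provider, self.config, labels=self.labels, seed=seed)

    @classmethod
    def from_corpus(cls, docs: list[Document], **kwargs) -> "BTNTagger":
        """Build from a pre-split corpus (documents carry their split_role)."""
        train = [d for d in docs if d.split_role == "train"]
        val = [d for d in docs if d.split_role == "validation"]
        return cls(train, val, **kwargs)

    def pretrain(self, unlabeled_docs: list[Document], epochs: int = 5, lr: float = 1e-4):
        """Run the TF-IDF-weighted-embedding pre-training stage in place."""
        table = normalize_tfidf(compute_tfidf(unlabeled_docs))
        state, record = run_pretraining(
            self.network, unlabeled_docs, epochs=epochs, lr=lr, seed=self.seed, table=table
        )
        self._pretrain_state, self._pretrain_record = state, record
        return record

    def fit(self, train_config: TrainConfig | None = None, init_state: dict | None = None):
        cfg = train_config or TrainConfig()
        record, state = train_ner(
            self.network, self.train_docs, self.val_docs, cfg,
            init_state=init_state, seed=self.seed,
        )
        return BTNResults(self, record, state, cfg)


@dataclass
class BTNResults:
    """Fit results: best-epoch checkpoint, loss/metric curves, evaluation."""

    model: BTNTagger
    record: RunRecord
    state: dict
    train_config: TrainConfig
    _reports: dict = field(default_factory=dict)

    def predict(self, sentence):
        return self.model.network.predict_spans(sentence)

    def evaluate(self, docs: list[Document]) -> dict[str, EvalReport]:
        key = tuple(d.id for d in docs)
        if key not in self._reports:
            self._reports[key] = evaluate_on(self.model.network, docs)
        return self._reports[key]

    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": range(len(self.record.train_losses)),
                "train_loss": self.record.train_losses,
                "val_exact_macro_f1": self.record.val_macro_f1,
            }
        )

    def summary(self, eval_docs: list[Document] | None = None) -> str:
        """Human-readable fit summary; optionally evaluates on held-out docs."""
        cfg = self.model.config
        lines = [
            "Character-level NER tagger (BiLSTM-Transformer-CRF)",
            "=" * 55,
            f"variant: {cfg.variant}   labels: {len(self.model.labels)}",
            f"lstm_hidden={cfg.lstm_hidden_size} x{cfg.lstm_layers}  "
            f"transformer={cfg.transformer_layers}L/{cfg.transformer_heads}H  "
            f"dropout={cfg.dropout}",
            f"epochs run: {len(self.record.train_losses)}   "
            f"best epoch: {self.record.best_epoch}   "
            f"best val exact macro-F1: {max(self.record.val_macro_f1):.4f}",
        ]
        if eval_docs is not None:
            reports = self.evaluate(eval_docs)
            for scheme in ("exact", "inexact"):
                r = reports[scheme]
                lines.append(
                    f"{scheme:>8} match: macro-F1 {r.macro['f1']:.4f}  "
                    f"micro-F1 {r.micro['f1']:.4f}"
                )
        return "\n".join(lines)
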