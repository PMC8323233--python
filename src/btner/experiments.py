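"""Reproducible protocol-level experiments on the synthetic fixture.

These runners wire the library modules into the three experiments the
package uses to validate its training pipeline end to end:

* :func:`pretraining_contracts` — run the unsupervised TF-IDF stage on the
  fixture corpus and report the loss curve plus freeze-contract checks.
* :func:`warm_cold_comparison` — pre-train once, then compare first-epoch
  supervised training loss of warm-started vs cold-started taggers across
  seeds (the convergence-benefit experiment).
* :func:`separable_benchmark` — train the full tagger on a separable
  synthetic corpus and score it on held-out documents under both match
  schemes.

Problem sizes default to the package's standard desk-scale settings; every
function is deterministic given its seeds.
"""

from __future__ import annotations

from .embeddings import EmbeddingMatrix, LookupProvider, Vocabulary
from .fixtures import FIXTURE_SEED, fixture_corpus
from .network import BtnModel, ModelConfig
from .pretraining import run_pretraining
from .synth import SynthConfig, generate_corpus
from .training import TrainConfig, evaluate_on, split_dataset, train_ner

#: Desk-scale network shape used by the experiments: the selected
#: hyperparameter point (1 LSTM layer, 1 Transformer layer, 1 head,
#: dropout 0.13, batch 8, lr 1e-4) with reduced widths (embedding 32,
#: hidden 64) so the experiments run on one CPU in minutes.
DESK_CONFIG = dict(embedding_dim=32, lstm_hidden_size=64, dropout=0.13)


def _build_model(docs, seed: int, vocab: Vocabulary | None = None) -> BtnModel:
    vocab = vocab or Vocabulary.from_documents(docs)
    cfg = ModelConfig(**DESK_CONFIG)
    matrix = EmbeddingMatrix.random(vocab, cfg.embedding_dim, seed=seed)
    return BtnModel(LookupProvider(vocab, matrix), cfg, seed=seed)


def pretraining_contracts(
    n_documents: int = 400, epochs: int = 5, seed: int = FIXTURE_SEED
) -> dict:
    """Pre-train on the fixture corpus and report contract checks.

    Returns per-epoch losses, whether every frozen component's checksum is
    unchanged, and whether the loss at the last epoch is below epoch 1.
    """
    docs = fixture_corpus(n_documents=n_documents)
    model = _build_model(docs, seed=seed)
    state, record = run_pretraining(model, docs, epochs=epochs, seed=seed)
    frozen_ok = all(
        record.checksums_before[c] == record.checksums_after[c]
        for c in ("embedding", "crf", "ner_head")
    )
    return {
        "epoch_losses": record.epoch_losses,
        "frozen_unchanged": frozen_ok,
        "loss_decreased": record.epoch_losses[-1] < record.epoch_losses[0],
        "state": state,
    }


def warm_cold_comparison(
    n_documents: int = 150,
    seeds: tuple[int, ...] = (0, 1, 2),
    pretrain_seed: int = FIXTURE_SEED,
    pretrain_epochs: int = 5,
) -> dict:
    """First-epoch supervised loss: warm start (pre-trained trunk) vs cold.

    Pre-trains once on the non-test splits of the fixture corpus, then for
    each seed trains a fresh tagger for one epoch from cold and from warm
    initialization and compares the epoch-1 mean training loss.
    """
    docs = fixture_corpus(n_documents=n_documents)
    train, val, _ = split_dataset(docs, seed=pretrain_seed)
    vocab = Vocabulary.from_documents(docs)
    pre_model = _build_model(docs, seed=pretrain_seed, vocab=vocab)
    state, _ = run_pretraining(pre_model, train + val, epochs=pretrain_epochs, seed=pretrain_seed)
    cfg = TrainConfig(learning_rate=1e-4, batch_size=8, max_epochs=1, patience=1)
    rows = []
    for s in seeds:
        cold, _ = train_ner(_build_model(docs, seed=s, vocab=vocab), train, val, cfg, seed=s)
        warm, _ = train_ner(
            _build_model(docs, seed=s, vocab=vocab), train, val, cfg,
            init_state=state, seed=s,
        )
        rows.append(
            {
                "seed": s,
                "cold_epoch1_loss": cold.train_losses[0],
                "warm_epoch1_loss": warm.train_losses[0],
                "warm_lower": warm.train_losses[0] < cold.train_losses[0],
            }
        )
    return {"runs": rows, "warm_wins": int(sum(r["warm_lower"] for r in rows))}


def separable_benchmark(
    n_documents: int = 130,
    max_train_sentences: int = 500,
    seed: int = FIXTURE_SEED,
    max_epochs: int = 30,
) -> dict:
    """Train the full tagger on a separable synthetic corpus.

    Uses disjoint per-type sublexicons (the generator default), caps the
    training split at ``max_train_sentences`` whole documents, trains with
    the standard protocol and evaluates on the held-out test split.
    """
    docs = generate_corpus(SynthConfig(n_documents=n_documents, seed=seed))
    train, val, test = split_dataset(docs, seed=seed)
    kept, count = [], 0
    for d in train:
        if count >= max_train_sentences:
            break
        kept.append(d)
        count += len(d.sentences)
    vocab = Vocabulary.from_documents(docs)
    model = _build_model(docs, seed=seed, vocab=vocab)
    cfg = TrainConfig(learning_rate=1e-4, batch_size=8, max_epochs=max_epochs, patience=max_epochs)
    record, _ = train_ner(model, kept, val, cfg, seed=seed)
    reports = evaluate_on(model, test)
    return {
        "n_train_sentences": count,
        "epochs_run": len(record.train_losses),
        "val_macro_f1": record.val_macro_f1,
        "test_exact_micro_f1": reports["exact"].micro["f1"],
        "test_exact_macro_f1": reports["exact"].macro["f1"],
        "test_inexact_micro_f1": reports["inexact"].micro["f1"],
        "test_inexact_macro_f1": reports["inexact"].macro["f1"],
    }
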