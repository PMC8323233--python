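"""End-to-end pipeline: generate -> split -> TF-IDF -> pretrain -> train ->
evaluate, with every artifact stamped by config hash and seed."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .corpus import AnnotatedSentence, Document, write_conll, write_standoff
from .embeddings import EmbeddingMatrix, LookupProvider, Vocabulary
from .network import BtnModel, ModelConfig
from .pretraining import compute_tfidf, normalize_tfidf, run_pretraining
from .synth import SynthConfig, generate_corpus
from .training import TrainConfig, split_dataset, train_ner


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    synth: SynthConfig | None = None
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        embedding_dim=32, lstm_hidden_size=64, transformer_dim=64, feedforward_dim=128
    ))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(seeds=(0,)))
    pretrain_epochs: int = 5
    pretraining: bool = True

    def hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "synth": asdict(self.synth) if self.synth else None,
                "model": asdict(self.model),
                "train": asdict(self.train),
                "pretraining": self.pretraining,
                "pretrain_epochs": self.pretrain_epochs,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def config_from_yaml(path, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Model/optimizer hyperparameters use their canonical names
    (``LSTM_Hidden_Size``, ``LSTM_Layer``, ``Transformer_Layer``,
    ``Transformer_Head``, ``Dropout``, ``Batch_size``, ``Learning_Rate``)
    under a ``model`` mapping; ``synth``, ``train`` and top-level keys
    (``seed``, ``out_dir``, ``pretraining``, ``pretrain_epochs``) are
    optional.  Keyword overrides (command-line flags) win over the file.
    """
    import yaml

    from .training import model_config_from_candidate

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    kwargs: dict = {}
    model_keys = dict(raw.get("model", {}))
    if model_keys:
        extra = {
            k: model_keys.pop(k)
            for k in ("embedding_dim", "variant")
            if k in model_keys
        }
        lr = model_keys.pop("Learning_Rate", None)
        batch = model_keys.pop("Batch_size", model_keys.pop("Batch_Size", None))
        kwargs["model"] = model_config_from_candidate(model_keys, **extra)
        train_kwargs = dict(raw.get("train", {}))
        if lr is not None:
            train_kwargs.setdefault("learning_rate", float(lr))
        if batch is not None:
            train_kwargs.setdefault("batch_size", int(batch))
        if train_kwargs:
            kwargs["train"] = TrainConfig(**train_kwargs)
    elif raw.get("train"):
        kwargs["train"] = TrainConfig(**raw["train"])
    if raw.get("synth"):
        kwargs["synth"] = SynthConfig(**raw["synth"])
    for key in ("seed", "out_dir", "pretraining", "pretrain_epochs"):
        if key in raw:
            kwargs[key] = raw[key]
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def _log(fh, **record):
    fh.write(json.dumps(record, default=float) + "\n")
    fh.flush()


def run_pipeline(config: PipelineConfig, docs: list[Document] | None = None) -> dict:
    """Execute the full pipeline; returns the final report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed, "time": time.time()}
    log = open(out / "pipeline.log.jsonl", "a", encoding="utf-8")

    def stage(name, fn):
        try:
            _log(log, stage=name, event="start", **stamp)
            result = fn()
            _log(log, stage=name, event="done", **stamp)
            return result
        except Exception as exc:  # abort with stage name and cause
            _log(log, stage=name, event="error", error=str(exc), **stamp)
            raise StageError(name, exc) from exc

    if docs is None:
        synth = config.synth or SynthConfig(n_documents=120, seed=config.seed)
        docs = stage("generate", lambda: generate_corpus(synth))
        stage("generate.write", lambda: write_conll(docs, out / "corpus.conll"))

    train_docs, val_docs, test_docs = stage(
        "split", lambda: split_dataset(docs, seed=config.seed)
    )
    vocab = Vocabulary.from_documents(docs)
    matrix = EmbeddingMatrix.random(vocab, config.model.embedding_dim, seed=config.seed)
    provider = LookupProvider(vocab, matrix, frozen=True)
    model = BtnModel(provider, config.model, seed=config.seed)

    init_state = None
    if config.pretraining:
        non_test = train_docs + val_docs

        def do_pretrain():
            table = normalize_tfidf(compute_tfidf(non_test))
            table.to_tsv(out / "tfidf.tsv")
            return run_pretraining(
                model, non_test, epochs=config.pretrain_epochs,
                seed=config.seed, table=table,
            )

        init_state, pre_record = stage("pretrain", do_pretrain)
        _log(log, stage="pretrain", event="losses", losses=pre_record.epoch_losses, **stamp)

    record, state = stage(
        "train",
        lambda: train_ner(model, train_docs, val_docs, config.train,
                          init_state=init_state, seed=config.seed),
    )
    for epoch, (loss, f1) in enumerate(zip(record.train_losses, record.val_macro_f1)):
        _log(log, stage="train", event="epoch", epoch=epoch, split="train",
             loss=loss, val_exact_macro_f1=f1, **stamp)
    (out / "checkpoint.json").write_text(json.dumps(state), encoding="utf-8")

    def do_evaluate():
        pred = [
            Document(d.id, [AnnotatedSentence(s.chars, model.predict_spans(s))
                            for s in d.sentences], d.split_role)
            for d in test_docs
        ]
        write_standoff(pred, out / "predictions.jsonl")
        from .evaluation import evaluate_both_schemes

        return evaluate_both_schemes(test_docs, pred)

    reports = stage("evaluate", do_evaluate)
    final = {
        **stamp,
        "splits": {"train": len(train_docs), "validation": len(val_docs), "test": len(test_docs)},
        "best_epoch": record.best_epoch,
        "val_exact_macro_f1": max(record.val_macro_f1),
        "test": {s: r.to_dict() for s, r in reports.items()},
    }
    (out / "report.json").write_text(json.dumps(final, indent=2), encoding="utf-8")
    log.close()
    return final
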