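"""The BiLSTM-Transformer-CRF tagging network and its ablation variants.

The full tagger ("btn") runs character embeddings through a BiLSTM (local,
order-sensitive context), then a Transformer encoder layer (global,
distance-independent dependencies), a linear emission head, and a
linear-chain CRF decoded by Viterbi.  Two ablations are first-class
variants: "bilstm_only" drops the Transformer, "transformer_only" drops the
BiLSTM (and therefore turns sinusoidal positional encodings on, since
self-attention alone is permutation-equivariant).

All path algebra (partition function, Viterbi, marginals) is carried out in
log space with max-subtraction.  Training-time quantities are built on the
:mod:`btner.autograd` tape; inference-time decoding is plain NumPy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import logsumexp as np_logsumexp

from .autograd import Parameter, Tensor, concat, no_grad, stack
from .corpus import bio_decode, bio_label_alphabet

VARIANTS = ("btn", "bilstm_only", "transformer_only")


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Hyperparameters of the tagging network.

    Defaults follow the selected operating point of the grid search:
    hidden size 128, one LSTM layer, one Transformer layer with one head,
    dropout 0.13.  ``transformer_dim`` (the Transformer width) defaults to
    the BiLSTM output width 2*hidden; the stack input is always projected
    to it.  ``feedforward_dim`` defaults to 4x the Transformer width.
    ``positional_encoding`` defaults to off for variants containing the
    BiLSTM (which already encodes order) and on for "transformer_only".
    """

    embedding_dim: int = 64
    lstm_hidden_size: int = 128
    lstm_layers: int = 1
    transformer_layers: int = 1
    transformer_heads: int = 1
    dropout: float = 0.13
    transformer_dim: int | None = None
    feedforward_dim: int | None = None
    variant: str = "btn"
    positional_encoding: bool | None = None
    use_layer_norm: bool = True
    use_crf: bool = True
    bio_transition_mask: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must lie in [0, 1)")
        if self.transformer_dim is None:
            self.transformer_dim = 2 * self.lstm_hidden_size
        if self.feedforward_dim is None:
            self.feedforward_dim = 4 * self.transformer_dim
        if self.transformer_dim % self.transformer_heads != 0:
            raise ConfigError("transformer_heads must divide the transformer width")
        if self.positional_encoding is None:
            self.positional_encoding = self.variant == "transformer_only"


def _glorot(rng, fan_in, fan_out, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Dense:
    def __init__(self, rng, d_in, d_out, name):
        self.W = Parameter(_glorot(rng, d_in, d_out), name=f"{name}.W")
        self.b = Parameter(np.zeros(d_out), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, dim, name, enabled=True):
        self.gamma = Parameter(np.ones(dim), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), name=f"{name}.beta")
        self.enabled = enabled
        self.eps = 1e-5

    def __call__(self, x: Tensor) -> Tensor:
        if not self.enabled:
            return x
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return self.gamma * ((x - mu) / (var + self.eps) ** 0.5) + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


def apply_dropout(x: Tensor, rate: float, rng, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float64) / (1.0 - rate)
    return x * Tensor(keep)


# ---------------------------------------------------------------------------
# BiLSTM
# ---------------------------------------------------------------------------

class LSTMDirection:
    """One direction of an LSTM; gate order i, f, g, o."""

    def __init__(self, rng, d_in, hidden, name):
        self.hidden = hidden
        self.Wx = Parameter(_glorot(rng, d_in, 4 * hidden), name=f"{name}.Wx")
        self.Wh = Parameter(_glorot(rng, hidden, 4 * hidden), name=f"{name}.Wh")
        self.b = Parameter(np.zeros(4 * hidden), name=f"{name}.b")

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        xW = x @ self.Wx + self.b  # input projection hoisted out of the loop
        outs = []
        for t in range(T):
            gates = xW[:, t, :] + h @ self.Wh
            i = gates[:, :H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            m = Tensor(mask[:, t : t + 1])
            h = h * m  # padded positions propagate zeros
            c = c * m
            outs.append(h)
        return stack(outs, axis=1)

    def parameters(self):
        return [self.Wx, self.Wh, self.b]


def _reverse_index(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays reversing each row within its true length."""
    B, T = mask.shape
    lengths = mask.sum(axis=1).astype(int)
    tidx = np.tile(np.arange(T), (B, 1))
    for b in range(B):
        L = lengths[b]
        tidx[b, :L] = L - 1 - np.arange(L)
    bidx = np.repeat(np.arange(B)[:, None], T, axis=1)
    return bidx, tidx


class BiLSTM:
    """Stack of bidirectional LSTM layers; output width 2*hidden."""

    def __init__(self, rng, d_in, hidden, n_layers, name="bilstm"):
        self.layers = []
        for l in range(n_layers):
            din = d_in if l == 0 else 2 * hidden
            fwd = LSTMDirection(rng, din, hidden, f"{name}.{l}.fwd")
            bwd = LSTMDirection(rng, din, hidden, f"{name}.{l}.bwd")
            self.layers.append((fwd, bwd))

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        bidx, tidx = _reverse_index(mask)
        for fwd, bwd in self.layers:
            hf = fwd(x, mask)
            x_rev = x[bidx, tidx]
            hb_rev = bwd(x_rev, mask)
            hb = hb_rev[bidx, tidx]
            x = concat([hf, hb], axis=-1)
        return x

    def parameters(self):
        return [p for fwd, bwd in self.layers for p in fwd.parameters() + bwd.parameters()]


# ---------------------------------------------------------------------------
# Transformer encoder layer (post-norm)
# ---------------------------------------------------------------------------

def sinusoidal_positions(T: int, dim: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


class TransformerLayer:
    """Multi-head self-attention + position-wise feed-forward, post-norm."""

    def __init__(self, rng, dim, heads, ff_dim, name="transformer", use_layer_norm=True):
        if dim % heads != 0:
            raise ConfigError("head count must divide model width")
        self.dim, self.heads = dim, heads
        self.Wq = Dense(rng, dim, dim, f"{name}.Wq")
        self.Wk = Dense(rng, dim, dim, f"{name}.Wk")
        self.Wv = Dense(rng, dim, dim, f"{name}.Wv")
        self.Wo = Dense(rng, dim, dim, f"{name}.Wo")
        self.ff1 = Dense(rng, dim, ff_dim, f"{name}.ff1")
        self.ff2 = Dense(rng, ff_dim, dim, f"{name}.ff2")
        self.ln1 = LayerNorm(dim, f"{name}.ln1", enabled=use_layer_norm)
        self.ln2 = LayerNorm(dim, f"{name}.ln2", enabled=use_layer_norm)

    def attention(self, x: Tensor, mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
        B, T, d = x.shape
        h, dk = self.heads, d // self.heads
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("attention mask excludes all positions for some sentence")

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, h, dk).transpose(0, 2, 1, 3)

        q, k, v = split_heads(self.Wq(x)), split_heads(self.Wk(x)), split_heads(self.Wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        bias = np.where(mask[:, None, None, :] > 0, 0.0, -1e9)
        att = (scores + Tensor(bias)).softmax(axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        return self.Wo(ctx), att.data

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        a, _ = self.attention(x, mask)
        x = self.ln1(x + a)
        f = self.ff2(self.ff1(x).relu())
        x = self.ln2(x + f)
        return x * Tensor(mask[:, :, None].astype(np.float64))

    def parameters(self):
        ps = []
        for part in (self.Wq, self.Wk, self.Wv, self.Wo, self.ff1, self.ff2, self.ln1, self.ln2):
            ps.extend(part.parameters())
        return ps

    def identity_init_(self):
        """Zero the attention-output and feed-forward output projections so the
        layer computes the identity (requires layer norm disabled)."""
        self.Wo.W.data[:] = 0.0
        self.Wo.b.data[:] = 0.0
        self.ff2.W.data[:] = 0.0
        self.ff2.b.data[:] = 0.0


# ---------------------------------------------------------------------------
# Linear-chain CRF
# ---------------------------------------------------------------------------

class CRF:
    """CRF over K labels with two extra START/STOP states.

    Transition table is (K+2, K+2); entry [a, b] scores a -> b.  With
    ``bio_mask`` set, transitions that violate the BIO grammar (e.g. O to
    I-T, or B-S to I-T with S != T) are hard-masked to -1e4; by default
    constraints are left to be learned from data.
    """

    def __init__(self, labels, bio_mask=False, name="crf"):
        self.labels = tuple(labels)
        K = len(labels)
        self.K = K
        self.start, self.stop = K, K + 1
        self.transitions = Parameter(np.zeros((K + 2, K + 2)), name=f"{name}.transitions")
        self._mask = self._build_mask() if bio_mask else None

    def _build_mask(self) -> np.ndarray:
        K = self.K
        m = np.zeros((K + 2, K + 2))
        for j, lab in enumerate(self.labels):
            if not lab.startswith("I-"):
                continue
            t = lab[2:]
            for i in range(K + 2):
                prev = self.labels[i] if i < K else None
                ok = prev is not None and prev in (f"B-{t}", f"I-{t}")
                if not ok:
                    m[i, j] = -1e4
        return m

    def _trans(self) -> Tensor:
        if self._mask is None:
            return self.transitions
        return self.transitions + Tensor(self._mask)

    def effective_transitions(self) -> np.ndarray:
        return self._trans().data

    def log_likelihood(self, emissions: Tensor, tags: np.ndarray) -> Tensor:
        """score(tags) - logZ for one sentence; emissions (L, K)."""
        L = emissions.shape[0]
        if L == 0:
            raise ValueError("empty sentence")
        tags = np.asarray(tags, dtype=int)
        trans = self._trans()
        prev = np.concatenate([[self.start], tags[:-1]])
        score = (
            emissions[np.arange(L), tags].sum()
            + trans[prev, tags].sum()
            + trans[tags[-1], self.stop]
        )
        alpha = emissions[0, :] + trans[self.start, : self.K]
        for t in range(1, L):
            step = alpha.reshape(self.K, 1) + trans[: self.K, : self.K] + emissions[t, :]
            alpha = step.logsumexp(axis=0)
        logZ = (alpha + trans[: self.K, self.stop]).logsumexp(axis=0)
        return score - logZ

    def batch_log_likelihood(
        self, emissions: Tensor, tags: np.ndarray, mask: np.ndarray
    ) -> Tensor:
        """Vectorized per-sentence log-likelihoods for a padded batch.

        ``emissions`` (B, T, K); ``tags`` (B, T) padded with 0; ``mask``
        (B, T) in {0, 1}.  Equals :meth:`log_likelihood` sentence-wise.
        """
        B, T, K = emissions.shape
        trans = self._trans()
        lengths = mask.sum(axis=1).astype(int)
        if (lengths == 0).any():
            raise ValueError("empty sentence in batch")
        bb = np.arange(B)
        bidx = np.repeat(bb[:, None], T, axis=1)
        tidx = np.tile(np.arange(T), (B, 1))
        mask_t = Tensor(mask)
        em_sel = emissions[bidx, tidx, tags]
        prev = np.concatenate([np.full((B, 1), self.start), tags[:, :-1]], axis=1)
        score = (
            (em_sel * mask_t).sum(axis=1)
            + (trans[prev, tags] * mask_t).sum(axis=1)
            + trans[tags[bb, lengths - 1], np.full(B, self.stop)]
        )
        alpha = emissions[:, 0, :] + trans[self.start, : self.K]
        for t in range(1, T):
            if not mask[:, t].any():
                break
            step = (
                alpha.reshape(B, K, 1)
                + trans[: self.K, : self.K].reshape(1, K, K)
                + emissions[:, t, :].reshape(B, 1, K)
            )
            new = step.logsumexp(axis=1)
            m = mask[:, t : t + 1]
            alpha = new * Tensor(m) + alpha * Tensor(1.0 - m)
        logZ = (alpha + trans[: self.K, self.stop]).logsumexp(axis=1)
        return score - logZ

    def viterbi(self, emissions: np.ndarray) -> tuple[list[int], float]:
        """Best path by max-product DP; ties break toward the lower tag index."""
        emissions = np.asarray(emissions, dtype=np.float64)
        L, K = emissions.shape
        if L == 0:
            raise ValueError("empty sentence")
        trans = self.effective_transitions()
        delta = emissions[0] + trans[self.start, :K]
        back = np.zeros((L, K), dtype=int)
        for t in range(1, L):
            cand = delta[:, None] + trans[:K, :K] + emissions[t][None, :]
            back[t] = np.argmax(cand, axis=0)  # argmax takes the first (lowest) index
            delta = cand[back[t], np.arange(K)]
        delta = delta + trans[:K, self.stop]
        best = int(np.argmax(delta))
        path = [best]
        for t in range(L - 1, 0, -1):
            best = int(back[t, best])
            path.append(best)
        path.reverse()
        return path, float(np.max(delta))

    def marginals(self, emissions: np.ndarray) -> np.ndarray:
        """Forward-backward per-position label marginals; rows sum to 1."""
        emissions = np.asarray(emissions, dtype=np.float64)
        L, K = emissions.shape
        if L == 0:
            raise ValueError("empty sentence")
        trans = self.effective_transitions()
        alpha = np.zeros((L, K))
        alpha[0] = emissions[0] + trans[self.start, :K]
        for t in range(1, L):
            alpha[t] = emissions[t] + np_logsumexp(
                alpha[t - 1][:, None] + trans[:K, :K], axis=0
            )
        beta = np.zeros((L, K))
        beta[L - 1] = trans[:K, self.stop]
        for t in range(L - 2, -1, -1):
            beta[t] = np_logsumexp(
                trans[:K, :K] + emissions[t + 1][None, :] + beta[t + 1][None, :], axis=1
            )
        logp = alpha + beta
        logp -= np_logsumexp(logp, axis=1, keepdims=True)
        return np.exp(logp)

    def parameters(self):
        return [self.transitions]


def crf_log_likelihood(emissions, transitions, tags) -> float:
    """Standalone log-likelihood on raw arrays (transitions (K+2, K+2))."""
    K = np.asarray(emissions).shape[1]
    crf = CRF([str(i) for i in range(K)])
    crf.transitions.data = np.asarray(transitions, dtype=np.float64)
    return float(crf.log_likelihood(Tensor(emissions), np.asarray(tags)).data)


def viterbi_decode(emissions, transitions):
    K = np.asarray(emissions).shape[1]
    crf = CRF([str(i) for i in range(K)])
    crf.transitions.data = np.asarray(transitions, dtype=np.float64)
    return crf.viterbi(emissions)


def marginal_probabilities(emissions, transitions=None) -> np.ndarray:
    """CRF forward-backward marginals, or plain softmax when transitions is None."""
    emissions = np.asarray(emissions, dtype=np.float64)
    if transitions is None:
        z = emissions - np_logsumexp(emissions, axis=1, keepdims=True)
        return np.exp(z)
    K = emissions.shape[1]
    crf = CRF([str(i) for i in range(K)])
    crf.transitions.data = np.asarray(transitions, dtype=np.float64)
    return crf.marginals(emissions)


# ---------------------------------------------------------------------------
# The model container
# ---------------------------------------------------------------------------

class BtnModel:
    """Parameter container for the tagger and its pre-training head.

    Components are addressable by name for freezing: ``embedding``,
    ``bilstm``, ``transformer``, ``projection``, ``ner_head``,
    ``pretrain_head``, ``crf``.  Exactly one head is active per mode
    ("ner" uses the label head + CRF; "pretrain" uses the tanh regression
    head of width D and never touches the CRF).
    """

    def __init__(self, provider, config: ModelConfig, labels=None, seed: int = 0):
        labels = tuple(labels) if labels is not None else bio_label_alphabet()
        config.embedding_dim = provider.dim
        self.provider = provider
        self.config = config
        self.labels = labels
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)

        D, d = provider.dim, config.transformer_dim
        self.bilstm = None
        if config.variant in ("btn", "bilstm_only"):
            self.bilstm = BiLSTM(rng, D, config.lstm_hidden_size, config.lstm_layers)
            proj_in = 2 * config.lstm_hidden_size
        else:
            proj_in = D
        self.projection = Dense(rng, proj_in, d, "projection")
        self.transformer = []
        if config.variant in ("btn", "transformer_only"):
            self.transformer = [
                TransformerLayer(
                    rng, d, config.transformer_heads, config.feedforward_dim,
                    name=f"transformer.{i}", use_layer_norm=config.use_layer_norm,
                )
                for i in range(config.transformer_layers)
            ]
        self.ner_head = Dense(rng, d, len(labels), "ner_head")
        self.pretrain_head = Dense(rng, d, D, "pretrain_head")
        self.crf = CRF(labels, bio_mask=config.bio_transition_mask)

    # ---- component registry -------------------------------------------
    def components(self) -> dict[str, list[Parameter]]:
        comp = {
            "embedding": list(self.provider.parameters()),
            "projection": self.projection.parameters(),
            "ner_head": self.ner_head.parameters(),
            "pretrain_head": self.pretrain_head.parameters(),
            "crf": self.crf.parameters(),
            "bilstm": self.bilstm.parameters() if self.bilstm else [],
            "transformer": [p for l in self.transformer for p in l.parameters()],
        }
        return comp

    def parameters(self) -> list[Parameter]:
        return [p for ps in self.components().values() for p in ps]

    def set_frozen(self, names, frozen=True):
        comp = self.components()
        for name in names:
            for p in comp[name]:
                p.frozen = frozen

    def set_mode(self, mode: str) -> None:
        """Set component freeze masks for "ner" or "pretrain" mode.

        NER mode trains the trunk, label head and CRF (the embedding table
        follows the provider's own frozen flag); pre-training mode trains
        only the trunk and the tanh regression head, freezing the embedding
        provider and the CRF.
        """
        if mode == "ner":
            self.set_frozen(("bilstm", "transformer", "projection", "ner_head", "crf"), False)
            self.set_frozen(("pretrain_head",), True)
            self.set_frozen(("embedding",), getattr(self.provider, "frozen", True))
        elif mode == "pretrain":
            self.set_frozen(("bilstm", "transformer", "projection", "pretrain_head"), False)
            self.set_frozen(("embedding", "ner_head", "crf"), True)
        else:
            raise ConfigError(f"unknown mode {mode!r}")

    def component_checksums(self) -> dict[str, float]:
        return {
            name: float(sum(float(np.abs(p.data).sum()) for p in ps))
            for name, ps in self.components().items()
        }

    # ---- forward passes -------------------------------------------------
    def _embed_batch(self, sentences) -> tuple[Tensor, np.ndarray]:
        """Pad sentences into a (B, T, D) tensor plus a (B, T) 0/1 mask."""
        B = len(sentences)
        T = max(len(s) for s in sentences)
        D = self.provider.dim
        mask = np.zeros((B, T))
        table = self.provider.static_table()
        trainable = table is not None and not table.param.frozen
        if trainable:
            idx = np.zeros((B, T), dtype=np.int64)
            for b, s in enumerate(sentences):
                idx[b, : len(s)] = self.provider.vocab.encode(s.chars)
                mask[b, : len(s)] = 1.0
            x = table.param[idx]
        else:
            arr = np.zeros((B, T, D))
            for b, s in enumerate(sentences):
                arr[b, : len(s)] = self.provider.embed(s.chars)
                mask[b, : len(s)] = 1.0
            x = Tensor(arr)
        return x, mask

    def trunk(self, sentences, training: bool = False) -> tuple[Tensor, np.ndarray]:
        """Shared stack up to (but not including) the output heads."""
        x, mask = self._embed_batch(sentences)
        rate = self.config.dropout
        x = apply_dropout(x, rate, self._dropout_rng, training)
        if self.bilstm is not None:
            x = self.bilstm(x, mask)
            x = apply_dropout(x, rate, self._dropout_rng, training)
        x = self.projection(x)
        if self.config.positional_encoding and self.transformer:
            x = x + Tensor(sinusoidal_positions(x.shape[1], x.shape[2]))
        for layer in self.transformer:
            x = layer(x, mask)
            x = apply_dropout(x, rate, self._dropout_rng, training)
        return x, mask

    def emissions(self, sentences, training: bool = False) -> tuple[Tensor, np.ndarray]:
        h, mask = self.trunk(sentences, training=training)
        return self.ner_head(h), mask

    def pretrain_outputs(self, sentences, training: bool = False) -> tuple[Tensor, np.ndarray]:
        h, mask = self.trunk(sentences, training=training)
        return self.pretrain_head(h).tanh(), mask

    def ner_loss(self, sentences, training: bool = True) -> Tensor:
        """Mean negative log-likelihood per sentence over the batch."""
        em, mask = self.emissions(sentences, training=training)
        if self.config.use_crf:
            B, T = mask.shape
            tags = np.zeros((B, T), dtype=int)
            for b, s in enumerate(sentences):
                tags[b, : len(s)] = [self.labels.index(t) for t in (s.tags or ())]
            return -self.crf.batch_log_likelihood(em, tags, mask).mean()
        losses = []
        for b, s in enumerate(sentences):
            tags = np.array([self.labels.index(t) for t in (s.tags or ())])
            logp = em[b, : len(s), :] - em[b, : len(s), :].logsumexp(axis=1, keepdims=True)
            losses.append(-(logp[np.arange(len(s)), tags].mean()))
        return stack(losses).mean()

    def predict_tags(self, sentence) -> list[str]:
        with no_grad():
            em, _ = self.emissions([sentence], training=False)
        e = em.data[0, : len(sentence), :]
        if self.config.use_crf:
            path, _ = self.crf.viterbi(e)
        else:
            path = list(np.argmax(e, axis=1))
        return [self.labels[i] for i in path]

    def predict_spans(self, sentence):
        return bio_decode(self.predict_tags(sentence), repair=True)

    # ---- checkpointing ---------------------------------------------------
    def _named_params(self) -> dict[str, Parameter]:
        return {p.name: p for p in self.parameters()}

    def state_dict(self) -> dict:
        vocab = getattr(self.provider, "vocab", None)
        return {
            "config": asdict(self.config),
            "labels": list(self.labels),
            "seed": self.seed,
            "vocabulary": list(vocab.itos[2:]) if vocab is not None else None,
            "params": {name: p.data.tolist() for name, p in self._named_params().items()},
            "shapes": {name: list(p.data.shape) for name, p in self._named_params().items()},
        }

    def load_state_dict(self, state: dict, strict: bool = True) -> None:
        named = self._named_params()
        for name, values in state["params"].items():
            if name not in named:
                if strict:
                    raise KeyError(f"unexpected parameter {name!r}")
                continue
            arr = np.asarray(values, dtype=np.float64)
            if list(arr.shape) != state["shapes"][name] or arr.shape != named[name].data.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            named[name].data = arr

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.state_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path, provider=None) -> "BtnModel":
        """Reload a checkpoint bit-exactly.

        Without an explicit provider, a static lookup provider is rebuilt
        from the vocabulary and embedding table stored in the checkpoint.
        """
        state = json.loads(Path(path).read_text(encoding="utf-8"))
        config = ModelConfig(**state["config"])
        if provider is None:
            from .embeddings import EmbeddingMatrix, LookupProvider, Vocabulary

            if state.get("vocabulary") is None:
                raise ValueError("checkpoint stores no vocabulary; pass a provider")
            vocab = Vocabulary(state["vocabulary"])
            table = np.asarray(state["params"]["embedding"], dtype=np.float64)
            provider = LookupProvider(vocab, EmbeddingMatrix(table))
        model = cls(provider, config, labels=state["labels"], seed=state["seed"])
        model.load_state_dict(state)
        return model

    def load_trunk_from(self, state: dict) -> None:
        """Warm-start the shared trunk (BiLSTM/Transformer/projection) only."""
        keep = ("bilstm", "transformer", "projection")
        named = self._named_params()
        for name, values in state["params"].items():
            if name.split(".")[0] in keep and name in named:
                named[name].data = np.asarray(values, dtype=np.float64)
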