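"""Network-layer behaviour: LSTM, Transformer layer, CRF exact inference.

CRF quantities are checked against an independent brute-force oracle that
enumerates all K^L tag paths.
"""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from btner.autograd import Adam, Tensor
from btner.network import (
    CRF,
    BiLSTM,
    BtnModel,
    ConfigError,
    LSTMDirection,
    ModelConfig,
    TransformerLayer,
    crf_log_likelihood,
    marginal_probabilities,
    sinusoidal_positions,
    viterbi_decode,
)


# ---------------------------------------------------------------------------
# Brute-force path enumeration oracle (independent of the CRF code)
# ---------------------------------------------------------------------------

def enumerate_paths(emissions, transitions):
    """Score every tag path including START/STOP transitions."""
    L, K = emissions.shape
    start, stop = K, K + 1
    paths = list(itertools.product(range(K), repeat=L))
    scores = []
    for path in paths:
        s = transitions[start, path[0]] + emissions[0, path[0]]
        for i in range(1, L):
            s += transitions[path[i - 1], path[i]] + emissions[i, path[i]]
        scores.append(s + transitions[path[-1], stop])
    return paths, np.array(scores)


def random_instance(rng, max_L=5, max_K=4):
    L = int(rng.integers(1, max_L + 1))
    K = int(rng.integers(1, max_K + 1))
    return rng.normal(size=(L, K)), rng.normal(size=(K + 2, K + 2))


class TestCRF:
    def test_single_label_log_likelihood_is_zero(self):
        em = np.array([[2.0], [1.0], [0.5]])
        tr = np.random.default_rng(0).normal(size=(3, 3))
        assert crf_log_likelihood(em, tr, [0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_step_two_label_hand_example(self):
        # emissions [[1,0],[0,1]], all transitions zero:
        # score(0,1) = 2, logZ = log(e^2 + 2e + 1)
        em = np.array([[1.0, 0.0], [0.0, 1.0]])
        tr = np.zeros((4, 4))
        expected = 2.0 - np.log(np.e**2 + 2 * np.e + 1)
        assert crf_log_likelihood(em, tr, [0, 1]) == pytest.approx(expected, abs=1e-12)
        path, score = viterbi_decode(em, tr)
        assert path == [0, 1] and score == pytest.approx(2.0)

    def test_path_probabilities_normalize(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            em, tr = random_instance(rng)
            L, K = em.shape
            total = sum(
                np.exp(crf_log_likelihood(em, tr, p))
                for p in itertools.product(range(K), repeat=L)
            )
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_log_likelihood_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            em, tr = random_instance(rng)
            paths, scores = enumerate_paths(em, tr)
            logZ = logsumexp(scores)
            tags = paths[int(rng.integers(len(paths)))]
            expected = scores[paths.index(tags)] - logZ
            assert crf_log_likelihood(em, tr, tags) == pytest.approx(expected, abs=1e-9)

    def test_viterbi_matches_enumeration_argmax(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            em, tr = random_instance(rng)
            paths, scores = enumerate_paths(em, tr)
            path, score = viterbi_decode(em, tr)
            assert score == pytest.approx(scores.max(), abs=1e-9)
            assert tuple(path) == paths[int(np.argmax(scores))]

    def test_viterbi_tie_breaks_toward_lower_index(self):
        em = np.zeros((2, 2))
        tr = np.zeros((4, 4))
        path, _ = viterbi_decode(em, tr)
        assert path == [0, 0]

    def test_marginals_match_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            em, tr = random_instance(rng)
            L, K = em.shape
            paths, scores = enumerate_paths(em, tr)
            probs = np.exp(scores - logsumexp(scores))
            ref = np.zeros((L, K))
            for pr, path in zip(probs, paths):
                for i, t in enumerate(path):
                    ref[i, t] += pr
            np.testing.assert_allclose(marginal_probabilities(em, tr), ref, atol=1e-9)

    def test_uniform_emissions_give_uniform_marginals(self):
        em = np.zeros((3, 4))
        tr = np.zeros((6, 6))
        np.testing.assert_allclose(marginal_probabilities(em, tr), 0.25, atol=1e-12)

    def test_softmax_marginals_without_transitions(self):
        em = np.array([[0.0, np.log(3.0)]])
        np.testing.assert_allclose(marginal_probabilities(em), [[0.25, 0.75]], atol=1e-12)

    def test_marginal_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        em, tr = rng.normal(size=(6, 5)), rng.normal(size=(7, 7))
        m = marginal_probabilities(em, tr)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_sequence_rejected(self):
        crf = CRF(["a", "b"])
        with pytest.raises(ValueError):
            crf.viterbi(np.zeros((0, 2)))

    def test_batched_equals_per_sentence(self):
        rng = np.random.default_rng(6)
        K, B, T = 4, 3, 5
        crf = CRF([str(i) for i in range(K)])
        crf.transitions.data = rng.normal(size=(K + 2, K + 2))
        lengths = [5, 2, 4]
        em = rng.normal(size=(B, T, K))
        mask = np.zeros((B, T))
        tags = np.zeros((B, T), dtype=int)
        for b, L in enumerate(lengths):
            mask[b, :L] = 1
            tags[b, :L] = rng.integers(0, K, L)
        batch = crf.batch_log_likelihood(Tensor(em), tags, mask).data
        for b, L in enumerate(lengths):
            single = crf.log_likelihood(Tensor(em[b, :L]), tags[b, :L]).item()
            assert batch[b] == pytest.approx(single, abs=1e-10)

    def test_bio_transition_mask_forbids_invalid_moves(self):
        crf = CRF(["O", "B-Mass", "I-Mass"], bio_mask=True)
        eff = crf.effective_transitions()
        assert eff[0, 2] <= -1e3  # O -> I-Mass
        assert eff[1, 2] == 0.0   # B-Mass -> I-Mass


class TestLSTM:
    def test_zero_weights_give_zero_outputs(self):
        rng = np.random.default_rng(0)
        cell = LSTMDirection(rng, 4, 3, "t")
        for p in cell.parameters():
            p.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 5, 4)))
        out = cell(x, np.ones((2, 5)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_no_recurrence_and_closed_forget_gate_is_positionwise(self):
        rng = np.random.default_rng(1)
        cell = LSTMDirection(rng, 4, 3, "t")
        cell.Wh.data[:] = 0.0
        cell.b.data[3 : 6] = -1e3  # forget gate shut: no cell-state carry
        x1 = rng.normal(size=(1, 4, 4))
        x2 = x1.copy()
        x2[0, :2] = rng.normal(size=(2, 4))  # change earlier inputs only
        o1 = cell(Tensor(x1), np.ones((1, 4))).data
        o2 = cell(Tensor(x2), np.ones((1, 4))).data
        np.testing.assert_allclose(o1[0, 3], o2[0, 3], atol=1e-12)

    def test_reversed_input_swaps_direction_halves(self):
        rng = np.random.default_rng(2)
        bi = BiLSTM(rng, 4, 3, 1)
        fwd, bwd = bi.layers[0]
        for pf, pb in zip(fwd.parameters(), bwd.parameters()):
            pb.data = pf.data.copy()  # shared weights across directions
        x = rng.normal(size=(1, 5, 4))
        out = bi(Tensor(x), np.ones((1, 5))).data
        out_rev = bi(Tensor(x[:, ::-1].copy()), np.ones((1, 5))).data
        np.testing.assert_allclose(out_rev[0, :, :3], out[0, ::-1, 3:], atol=1e-12)

    def test_masked_positions_propagate_zeros(self):
        rng = np.random.default_rng(3)
        cell = LSTMDirection(rng, 4, 3, "t")
        mask = np.array([[1.0, 1.0, 0.0, 0.0]])
        out = cell(Tensor(rng.normal(size=(1, 4, 4))), mask)
        np.testing.assert_array_equal(out.data[0, 2:], 0.0)


class TestTransformerLayer:
    def _layer(self, dim=8, heads=2, seed=0, use_ln=True):
        return TransformerLayer(np.random.default_rng(seed), dim, heads, 16,
                                use_layer_norm=use_ln)

    def test_length_one_attention_weight_is_exactly_one(self):
        layer = self._layer()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 1, 8)))
        _, att = layer.attention(x, np.ones((1, 1)))
        np.testing.assert_array_equal(att, 1.0)

    def test_identical_positions_give_identical_outputs(self):
        layer = self._layer()
        row = np.random.default_rng(2).normal(size=8)
        x = Tensor(np.tile(row, (1, 5, 1)))
        out = layer(x, np.ones((1, 5))).data
        for t in range(1, 5):
            np.testing.assert_allclose(out[0, t], out[0, 0], atol=1e-10)

    def test_permutation_equivariance_without_positional_encoding(self):
        layer = self._layer()
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 6, 8))
        perm = rng.permutation(6)
        out = layer(Tensor(x), np.ones((1, 6))).data
        out_p = layer(Tensor(x[:, perm]), np.ones((1, 6))).data
        np.testing.assert_allclose(out_p[0], out[0, perm], atol=1e-10)

    def test_positional_encoding_breaks_permutation_equivariance(self):
        layer = self._layer()
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 6, 8))
        pe = sinusoidal_positions(6, 8)
        perm = np.array([5, 0, 1, 2, 3, 4])
        out = layer(Tensor(x + pe), np.ones((1, 6))).data
        out_p = layer(Tensor(x[:, perm] + pe), np.ones((1, 6))).data
        assert not np.allclose(out_p[0], out[0, perm], atol=1e-6)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        layer = self._layer()
        for _ in range(100):
            T = int(rng.integers(1, 7))
            x = Tensor(rng.normal(size=(1, T, 8)))
            _, att = layer.attention(x, np.ones((1, T)))
            np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)

    def test_all_masked_rejected(self):
        layer = self._layer()
        with pytest.raises(ValueError, match="mask"):
            layer(Tensor(np.zeros((1, 3, 8))), np.zeros((1, 3)))

    def test_head_count_must_divide_width(self):
        with pytest.raises(ConfigError):
            self._layer(dim=8, heads=3)


class TestModel:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError, match="variant"):
            ModelConfig(variant="cnn")

    def test_forward_deterministic_without_dropout(self, tiny_model_factory, small_corpus):
        m = tiny_model_factory(dropout=0.0)
        sent = small_corpus[0].sentences[0]
        assert m.predict_tags(sent) == m.predict_tags(sent)

    def test_predicted_spans_always_valid(self, tiny_model_factory, small_corpus):
        m = tiny_model_factory()
        for doc in small_corpus[:5]:
            for sent in doc.sentences:
                spans = m.predict_spans(sent)
                ends = sorted((s.start, s.end) for s in spans)
                for (s1, e1), (s2, e2) in zip(ends, ends[1:]):
                    assert e1 <= s2
                assert all(0 <= s.start < s.end <= len(sent) for s in spans)

    def test_bilstm_only_equals_btn_with_identity_transformer(
        self, tiny_model_factory, small_corpus
    ):
        btn = tiny_model_factory(variant="btn", use_layer_norm=False)
        for layer in btn.transformer:
            layer.identity_init_()
        plain = tiny_model_factory(variant="bilstm_only", use_layer_norm=False)
        plain.load_state_dict(btn.state_dict(), strict=False)
        sent = small_corpus[0].sentences[0]
        e1, _ = btn.emissions([sent])
        e2, _ = plain.emissions([sent])
        np.testing.assert_allclose(e1.data, e2.data, atol=1e-12)

    def test_transformer_only_uses_positional_encodings_by_default(self):
        assert ModelConfig(variant="transformer_only").positional_encoding
        assert not ModelConfig(variant="btn").positional_encoding

    def test_checkpoint_round_trip_bit_exact(self, tiny_model_factory, tmp_path):
        m = tiny_model_factory(seed=5)
        path = tmp_path / "ckpt.json"
        m.save(path)
        m2 = BtnModel.load(path, m.provider)
        for a, b in zip(m.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_checkpoint_rebuilds_provider_from_stored_vocabulary(
        self, tiny_model_factory, small_corpus, tmp_path
    ):
        m = tiny_model_factory(seed=5)
        path = tmp_path / "ckpt.json"
        m.save(path)
        m2 = BtnModel.load(path)  # no provider passed
        sent = small_corpus[0].sentences[0]
        assert m.predict_tags(sent) == m2.predict_tags(sent)

    def test_frozen_provider_untouched_by_training_step(self, tiny_model_factory, small_corpus):
        m = tiny_model_factory()
        m.provider.frozen = True
        m.set_mode("ner")
        before = m.provider.matrix.data.copy()
        sents = [s for d in small_corpus[:2] for s in d.sentences][:4]
        opt = Adam(m.parameters(), lr=1e-3)
        loss = m.ner_loss(sents, training=True)
        loss.backward()
        opt.step()
        np.testing.assert_array_equal(m.provider.matrix.data, before)
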