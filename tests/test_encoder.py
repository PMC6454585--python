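"""Encoder: attention contract, naive-loop oracles for the recurrent layers,
batching/padding equivalence and the end-to-end gradient check."""

import numpy as np
import pytest

from charner import autograd as ag
from charner.autograd import Tensor
from charner.corpus_io import AnnotatedSentence
from charner.encoder import (
    AttentionParams,
    attention_pool,
    attention_weights,
    context_encode,
    embed,
    encode_inputs,
    init_encoder_params,
    project_emissions,
    self_match_encode,
)
from charner.model import SelfMatchingTagger, TrainConfig


def make_attention(rng, k, d):
    return AttentionParams(
        w=Tensor(rng.normal(size=k)),
        W_v=Tensor(rng.normal(size=(k, d))),
        W_vhat=Tensor(rng.normal(size=(k, d))),
    )


def naive_attention(V, t, att):
    """Scalar-by-scalar transcription of the attention equations: scores
    s_j = w . tanh(W_v v_j + W_vhat v_t), softmax weights, pooled vector."""
    m, d = V.shape
    k = att.w.data.shape[0]
    s = np.zeros(m)
    for j in range(m):
        pre = np.zeros(k)
        for a in range(k):
            for b in range(d):
                pre[a] += att.W_v.data[a, b] * V[j, b]
                pre[a] += att.W_vhat.data[a, b] * V[t, b]
        s[j] = sum(att.w.data[a] * np.tanh(pre[a]) for a in range(k))
    e = np.exp(s - s.max())
    a_w = e / e.sum()
    c = np.zeros(d)
    for i in range(m):
        c += a_w[i] * V[i]
    return a_w, c


def naive_lstm(W, b, inputs, reverse=False):
    """Per-step loop LSTM with explicit gate arithmetic (zero init states)."""
    m, d = inputs.shape
    k = b.shape[0] // 4
    h = np.zeros(k)
    c = np.zeros(k)
    out = np.zeros((m, k))
    order = range(m - 1, -1, -1) if reverse else range(m)
    for t in order:
        z = np.concatenate([inputs[t], h]) @ W + b
        i = 1 / (1 + np.exp(-z[:k]))
        f = 1 / (1 + np.exp(-z[k:2 * k]))
        g = np.tanh(z[2 * k:3 * k])
        o = 1 / (1 + np.exp(-z[3 * k:]))
        c = f * c + i * g
        h = o * np.tanh(c)
        out[t] = h
    return out


class TestEmbed:
    def test_shapes_with_and_without_pos(self, rng):
        ct = rng.normal(size=(6, 4))
        pt = rng.normal(size=(5, 4))
        V = embed([1, 3], [0, 2], ct, pt)
        assert V.shape == (2, 8)
        V1 = embed([2], None, ct)
        assert V1.shape == (1, 4)
        np.testing.assert_array_equal(V1[0], ct[2])

    def test_one_hot_lookup(self):
        ct = np.eye(3)
        pt = 2 * np.eye(3)
        V = embed([0, 2], [1, 1], ct, pt)
        np.testing.assert_array_equal(V[0], [1, 0, 0, 0, 2, 0])
        np.testing.assert_array_equal(V[1], [0, 0, 1, 0, 2, 0])

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            embed([5], None, np.zeros((3, 2)))


class TestAttention:
    def test_singleton_softmax(self, rng):
        att = make_attention(rng, 3, 2)
        V = rng.normal(size=(1, 2))
        np.testing.assert_allclose(attention_weights(V, 0, att), [1.0])
        np.testing.assert_allclose(attention_pool(V, 0, att), V[0])

    def test_identical_rows_give_uniform_weights(self, rng):
        att = make_attention(rng, 4, 3)
        V = np.tile(rng.normal(size=(1, 3)), (5, 1))
        np.testing.assert_allclose(attention_weights(V, 2, att),
                                   np.full(5, 0.2), atol=1e-12)

    def test_three_position_hand_worked_example(self):
        """Integer-parameter 3-position example checked against a pure
        scalar-loop transcription of the attention equations."""
        att = AttentionParams(
            w=Tensor(np.array([1.0, -2.0])),
            W_v=Tensor(np.array([[1.0, 0.0], [0.0, 1.0]])),
            W_vhat=Tensor(np.array([[0.0, 1.0], [1.0, 0.0]])),
        )
        V = np.array([[0.5, -1.0], [1.0, 1.0], [-0.5, 0.0]])
        for t in range(3):
            a_naive, c_naive = naive_attention(V, t, att)
            np.testing.assert_allclose(attention_weights(V, t, att), a_naive,
                                       atol=1e-10)
            np.testing.assert_allclose(attention_pool(V, t, att), c_naive,
                                       atol=1e-10)

    def test_weights_form_a_probability_simplex(self, rng):
        for _ in range(25):
            m, d, k = rng.integers(1, 7), rng.integers(1, 5), rng.integers(1, 5)
            att = make_attention(rng, k, d)
            V = rng.normal(scale=3.0, size=(m, d))
            for t in range(m):
                a = attention_weights(V, t, att)
                assert np.all(a >= 0)
                assert abs(a.sum() - 1.0) < 1e-6

    def test_bad_position_rejected(self, rng):
        att = make_attention(rng, 2, 2)
        with pytest.raises(IndexError):
            attention_weights(rng.normal(size=(3, 2)), 3, att)


def tiny_params(rng, d=3, k=2, n=4):
    """Hand-shaped EncoderParams over raw input rows of width d."""
    return init_encoder_params(rng, n_chars=5, n_pos=None, n_labels=n,
                               emb_dim=d, hidden=k)


class TestSelfMatchEncode:
    def test_zero_input_zero_params_fixed_point(self):
        """With zero parameters the LSTM gate preactivations vanish, so cell
        and hidden states stay exactly zero."""
        rng = np.random.default_rng(0)
        params = tiny_params(rng, d=3, k=2)
        for t in params.tensors():
            t.data[...] = 0.0
        H = self_match_encode(np.zeros((4, 3)), params)
        np.testing.assert_array_equal(H, np.zeros((4, 4)))
        L = context_encode(H, params)
        np.testing.assert_array_equal(L, np.zeros((4, 4)))

    def test_m1_uses_its_own_vector_as_context(self, rng):
        """At m=1 the attention pool is v_1 itself, so H equals one forward
        and one backward LSTM step on [v_1, v_1]."""
        params = tiny_params(rng, d=3, k=2)
        V = rng.normal(size=(1, 3))
        H = self_match_encode(V, params)
        u = np.concatenate([V[0], V[0]])[None, :]
        hf = naive_lstm(params.fwd.W.data, params.fwd.b.data, u)
        hb = naive_lstm(params.bwd.W.data, params.bwd.b.data, u, reverse=True)
        np.testing.assert_allclose(H, np.concatenate([hf, hb], axis=1),
                                   atol=1e-12)

    def test_naive_loop_oracle_m4(self, rng):
        """Both directions agree with an explicit per-step loop over
        [v_t, c_t]; the backward pass equals running the forward machinery on
        the reversed sequence and flipping the result."""
        params = tiny_params(rng, d=3, k=2)
        V = rng.normal(size=(4, 3))
        U = np.stack([
            np.concatenate([V[t], attention_pool(V, t, params.att)])
            for t in range(4)
        ])
        hf = naive_lstm(params.fwd.W.data, params.fwd.b.data, U)
        hb = naive_lstm(params.bwd.W.data, params.bwd.b.data, U, reverse=True)
        H = self_match_encode(V, params)
        np.testing.assert_allclose(H, np.concatenate([hf, hb], axis=1),
                                   atol=1e-10)
        # reversal property of the backward direction
        hb_flip = naive_lstm(params.bwd.W.data, params.bwd.b.data, U[::-1])[::-1]
        np.testing.assert_allclose(hb, hb_flip, atol=1e-12)

    def test_context_encode_naive_oracle_m5(self, rng):
        params = tiny_params(rng, d=3, k=2)
        H = rng.normal(size=(5, 4))
        L = context_encode(H, params)
        lf = naive_lstm(params.ctx_fwd.W.data, params.ctx_fwd.b.data, H)
        lb = naive_lstm(params.ctx_bwd.W.data, params.ctx_bwd.b.data, H,
                        reverse=True)
        np.testing.assert_allclose(L, np.concatenate([lf, lb], axis=1),
                                   atol=1e-10)
        assert L.shape == (5, 4)


class TestProjectEmissions:
    def test_zero_features_give_bias_rows(self, rng):
        b = rng.normal(size=4)
        E = project_emissions(np.zeros((3, 5)), rng.normal(size=(5, 4)), b)
        np.testing.assert_allclose(E, np.tile(b, (3, 1)))

    def test_single_label_degenerate(self, rng):
        E = project_emissions(rng.normal(size=(3, 2)), rng.normal(size=(2, 1)),
                              rng.normal(size=1))
        assert E.shape == (3, 1)

    def test_naive_matmul_oracle(self, rng):
        L = rng.normal(size=(3, 4))
        W = rng.normal(size=(4, 2))
        b = rng.normal(size=2)
        expected = np.zeros((3, 2))
        for i in range(3):
            for j in range(2):
                expected[i, j] = b[j] + sum(L[i, kk] * W[kk, j] for kk in range(4))
        np.testing.assert_allclose(project_emissions(L, W, b), expected,
                                   atol=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            project_emissions(np.zeros((3, 4)), np.zeros((5, 2)), np.zeros(2))


class TestBatchingAndPadding:
    def test_batched_equals_single_sentence(self, rng):
        """Padded batch execution must agree with per-sentence execution to
        1e-5: padding is masked out of attention, recurrence and emissions."""
        params = tiny_params(rng, d=3, k=2, n=4)
        lengths = [5, 2, 3]
        Vs = [rng.normal(size=(m, 3)) for m in lengths]
        m_max = max(lengths)
        batch = np.zeros((3, m_max, 3))
        mask = np.zeros((3, m_max))
        for i, V in enumerate(Vs):
            batch[i, :len(V)] = V
            mask[i, :len(V)] = 1.0
        batched = encode_inputs(Tensor(batch), params, mask).data
        for i, V in enumerate(Vs):
            single = encode_inputs(Tensor(V[None]), params,
                                   np.ones((1, len(V)))).data[0]
            np.testing.assert_allclose(batched[i, :len(V)], single, atol=1e-5)

    def test_determinism(self, rng):
        params = tiny_params(rng, d=3, k=2, n=4)
        V = rng.normal(size=(1, 4, 3))
        mask = np.ones((1, 4))
        a = encode_inputs(Tensor(V), params, mask).data
        b = encode_inputs(Tensor(V), params, mask).data
        np.testing.assert_array_equal(a, b)


class TestEndToEndGradient:
    def test_finite_difference_check_tiny_model(self):
        """Autograd gradient of the full encoder+CRF loss on a tiny model
        agrees with central finite differences to 1e-4 relative error (per
        parameter, on gradient vectors)."""
        sents = [
            AnnotatedSentence(chars=list("abc"), pos=list("nnv"),
                              labels=["O", "B_ana", "I_ana"]),
            AnnotatedSentence(chars=list("ba"), pos=list("vn"),
                              labels=["B_dru", "I_dru"]),
        ]
        cfg = TrainConfig(input_mode="char+pos", char_embedding_size=3,
                          pos_embedding_size=3, hidden_units=2, seed=3)
        model = SelfMatchingTagger.build(cfg, sents)
        loss = model.loss_batch(sents)
        loss.backward()
        eps = 1e-6
        auto_all, fd_all = [], []
        for p in model.params.tensors() + [model.transitions]:
            auto = p.grad if p.grad is not None else np.zeros_like(p.data)
            fd = np.zeros_like(p.data)
            it = np.nditer(p.data, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = p.data[ix]
                p.data[ix] = old + eps
                lp = model.loss_batch(sents).item()
                p.data[ix] = old - eps
                lm = model.loss_batch(sents).item()
                p.data[ix] = old
                fd[ix] = (lp - lm) / (2 * eps)
            # elementwise check with an absolute floor for entries whose
            # finite difference drowns in float64 roundoff
            np.testing.assert_allclose(auto, fd, rtol=1e-4, atol=1e-6)
            auto_all.append(auto.ravel())
            fd_all.append(fd.ravel())
        auto_vec = np.concatenate(auto_all)
        fd_vec = np.concatenate(fd_all)
        rel = np.linalg.norm(fd_vec - auto_vec) / np.linalg.norm(fd_vec)
        assert rel < 1e-4
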