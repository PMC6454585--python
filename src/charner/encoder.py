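"""Sentence encoder: embeddings, self-matching attention, BiLSTMs, emissions.

The encoder maps an m-character sentence to an m x n matrix of unnormalized
per-character label scores ("emissions") in four stages:

1. *Embedding.*  Character vectors x_t (dimension l), optionally
   concatenated with POS vectors p_t of the same dimension, give input rows
   v_t (width d = l or 2l).
2. *Self-matching attention.*  For every position t, a score
   ``s_j^t = w^T tanh(W_v v_j + W_vhat v_t)`` is computed against every
   position j of the same sentence; softmax weights a^t over j yield an
   attention-pooling vector ``c_t = sum_j a_j^t v_j``.  Attention operates
   on the raw input rows, and c_t is shared by both recurrent directions.
3. *Recurrent encoding.*  A bidirectional LSTM consumes [v_t, c_t] at each
   step (the self-matching layer, output H, width 2k), and a second
   bidirectional LSTM re-encodes H into context features L (width 2k).
4. *Projection.*  ``emissions = L W_p + b_p`` (shape m x n).

All heavy lifting runs batched on the autograd Tensor type with right-padded
sentences; padded positions are excluded from the attention softmax, frozen
out of the recurrent state updates, and masked in the CRF loss.  The
module-level functions (:func:`embed`, :func:`attention_pool`,
:func:`self_match_encode`, :func:`context_encode`,
:func:`project_emissions`) are single-sentence NumPy conveniences over the
same code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "AttentionParams",
    "LSTMParams",
    "EncoderParams",
    "init_encoder_params",
    "embed",
    "attention_pool",
    "attention_weights",
    "self_match_encode",
    "context_encode",
    "project_emissions",
    "encode_inputs",
    "lstm_scan",
]

#: Uniform initialization half-width for all weight matrices and embeddings.
INIT_SCALE = 0.1


@dataclass
class AttentionParams:
    """Self-matching attention parameters: w (k,), W_v (k, d), W_vhat (k, d)."""

    w: Tensor
    W_v: Tensor
    W_vhat: Tensor

    def __post_init__(self) -> None:
        k, d = self.W_v.shape
        if self.W_vhat.shape != (k, d) or self.w.shape != (k,):
            raise ValueError("inconsistent attention parameter shapes")
        for t in (self.w, self.W_v, self.W_vhat):
            if not np.all(np.isfinite(t.data)):
                raise ValueError("attention parameters must be finite")


@dataclass
class LSTMParams:
    """One LSTM direction: W ((d_in + k), 4k) and b (4k,), gate order i,f,g,o."""

    W: Tensor
    b: Tensor

    @property
    def hidden(self) -> int:
        return self.W.shape[1] // 4


@dataclass
class EncoderParams:
    """All encoder parameters; ``pos_emb`` is None in character-only mode."""

    char_emb: Tensor
    pos_emb: Tensor | None
    att: AttentionParams
    fwd: LSTMParams
    bwd: LSTMParams
    ctx_fwd: LSTMParams
    ctx_bwd: LSTMParams
    W_p: Tensor
    b_p: Tensor

    def tensors(self) -> list[Tensor]:
        out = [self.char_emb]
        if self.pos_emb is not None:
            out.append(self.pos_emb)
        out += [self.att.w, self.att.W_v, self.att.W_vhat]
        for lp in (self.fwd, self.bwd, self.ctx_fwd, self.ctx_bwd):
            out += [lp.W, lp.b]
        out += [self.W_p, self.b_p]
        return out


def _uniform(rng: np.random.Generator, *shape: int) -> Tensor:
    return Tensor(rng.uniform(-INIT_SCALE, INIT_SCALE, size=shape), requires_grad=True)


def init_encoder_params(
    rng: np.random.Generator,
    n_chars: int,
    n_pos: int | None,
    n_labels: int,
    emb_dim: int = 50,
    hidden: int = 200,
    att_dim: int | None = None,
) -> EncoderParams:
    """Random initialization: uniform(-0.1, 0.1) weights/embeddings, zero
    biases, zero initial recurrent states.  ``att_dim`` (rows of W_v)
    defaults to the LSTM hidden size."""
    d = emb_dim * (2 if n_pos else 1)
    k_att = att_dim or hidden
    att = AttentionParams(
        w=_uniform(rng, k_att),
        W_v=_uniform(rng, k_att, d),
        W_vhat=_uniform(rng, k_att, d),
    )

    def lstm(d_in: int) -> LSTMParams:
        return LSTMParams(
            W=_uniform(rng, d_in + hidden, 4 * hidden),
            b=Tensor(np.zeros(4 * hidden), requires_grad=True),
        )

    return EncoderParams(
        char_emb=_uniform(rng, n_chars, emb_dim),
        pos_emb=_uniform(rng, n_pos, emb_dim) if n_pos else None,
        att=att,
        fwd=lstm(2 * d),
        bwd=lstm(2 * d),
        ctx_fwd=lstm(2 * hidden),
        ctx_bwd=lstm(2 * hidden),
        W_p=_uniform(rng, 2 * hidden, n_labels),
        b_p=Tensor(np.zeros(n_labels), requires_grad=True),
    )


# ---------------------------------------------------------------------------
# batched Tensor pipeline
# ---------------------------------------------------------------------------

def attention_batch(V: Tensor, att: AttentionParams, mask: np.ndarray) -> Tensor:
    """Attention-pooling vectors C (B, m, d) for padded input rows V (B, m, d).

    Padded key positions are pushed to -1e9 before the softmax, so their
    weight underflows to zero.
    """
    A_keys = ag.matmul(V, ag.swapaxes(att.W_v, 0, 1))      # (B, m, k): W_v v_j
    A_query = ag.matmul(V, ag.swapaxes(att.W_vhat, 0, 1))  # (B, m, k): W_vhat v_t
    # scores[b, t, j] = w . tanh(W_v v_j + W_vhat v_t)
    scores = ag.inner_last(
        ag.tanh(ag.expand_dims(A_keys, 1) + ag.expand_dims(A_query, 2)), att.w
    )
    bias = (mask[:, None, :] - 1.0) * 1e9
    weights = ag.softmax(scores + Tensor(bias), axis=2)    # (B, m, m)
    return ag.matmul(weights, V)


def lstm_scan(params: LSTMParams, inputs: Tensor, mask: np.ndarray,
              reverse: bool = False) -> Tensor:
    """Run one LSTM direction over a padded batch.

    ``inputs`` is (B, m, d_in); returns hidden states (B, m, k) aligned with
    the input positions.  At masked steps the state carries over unchanged,
    so right-padding never contaminates the backward direction.
    """
    B, m, _ = inputs.shape
    k = params.hidden
    h = Tensor(np.zeros((B, k)))
    c = Tensor(np.zeros((B, k)))
    outputs: list[Tensor | None] = [None] * m
    order = range(m - 1, -1, -1) if reverse else range(m)
    for t in order:
        x = inputs[:, t, :]
        z = ag.matmul(ag.concatenate([x, h], axis=1), params.W) + params.b
        i = ag.sigmoid(z[:, :k])
        f = ag.sigmoid(z[:, k:2 * k])
        g = ag.tanh(z[:, 2 * k:3 * k])
        o = ag.sigmoid(z[:, 3 * k:])
        c_new = f * c + i * g
        h_new = o * ag.tanh(c_new)
        mt = mask[:, t:t + 1]
        if np.all(mt == 1.0):
            c, h = c_new, h_new
        else:
            c = Tensor(mt) * c_new + Tensor(1.0 - mt) * c
            h = Tensor(mt) * h_new + Tensor(1.0 - mt) * h
        outputs[t] = h
    return ag.stack(outputs, axis=1)


def self_match_batch(V: Tensor, params: EncoderParams, mask: np.ndarray) -> Tensor:
    """Self-matching layer: BiLSTM over [v_t, c_t]; output H (B, m, 2k)."""
    C = attention_batch(V, params.att, mask)
    U = ag.concatenate([V, C], axis=2)
    hf = lstm_scan(params.fwd, U, mask, reverse=False)
    hb = lstm_scan(params.bwd, U, mask, reverse=True)
    return ag.concatenate([hf, hb], axis=2)


def context_batch(H: Tensor, params: EncoderParams, mask: np.ndarray) -> Tensor:
    """Context layer: plain BiLSTM re-encoding of H; output L (B, m, 2k)."""
    lf = lstm_scan(params.ctx_fwd, H, mask, reverse=False)
    lb = lstm_scan(params.ctx_bwd, H, mask, reverse=True)
    return ag.concatenate([lf, lb], axis=2)


def encode_inputs(V: Tensor, params: EncoderParams, mask: np.ndarray) -> Tensor:
    """Full encoder from input rows V (B, m, d) to emissions (B, m, n)."""
    H = self_match_batch(V, params, mask)
    L = context_batch(H, params, mask)
    return ag.matmul(L, params.W_p) + params.b_p


# ---------------------------------------------------------------------------
# single-sentence NumPy surface
# ---------------------------------------------------------------------------

def _full_mask(m: int) -> np.ndarray:
    return np.ones((1, m))


def embed(char_ids: Sequence[int], pos_ids: Sequence[int] | None,
          char_table: np.ndarray, pos_table: np.ndarray | None = None) -> np.ndarray:
    """Look up input rows V for one sentence.

    Returns (m, 2l) when POS indices and table are given (rows are
    [x_t, p_t]), else (m, l).
    """
    char_ids = np.asarray(char_ids, dtype=np.intp)
    if char_ids.size and (char_ids.min() < 0 or char_ids.max() >= len(char_table)):
        raise IndexError("character index out of embedding-table range")
    X = np.asarray(char_table)[char_ids]
    if pos_ids is None:
        return X
    if pos_table is None:
        raise ValueError("POS indices given without a POS embedding table")
    pos_ids = np.asarray(pos_ids, dtype=np.intp)
    if pos_ids.shape != char_ids.shape:
        raise ValueError("character and POS index sequences differ in length")
    if pos_ids.size and (pos_ids.min() < 0 or pos_ids.max() >= len(pos_table)):
        raise IndexError("POS index out of embedding-table range")
    P = np.asarray(pos_table)[pos_ids]
    return np.concatenate([X, P], axis=1)


def attention_weights(V: np.ndarray, t: int, att: AttentionParams) -> np.ndarray:
    """Softmax attention weights a^t over all positions, for position t
    (0-based)."""
    V = np.asarray(V, dtype=np.float64)
    m = V.shape[0]
    if m == 0:
        raise ValueError("attention over an empty sentence")
    if not 0 <= t < m:
        raise IndexError(f"position {t} outside [0, {m})")
    s = att.w.data @ np.tanh(att.W_v.data @ V.T + (att.W_vhat.data @ V[t])[:, None])
    s = s - s.max()
    e = np.exp(s)
    return e / e.sum()


def attention_pool(V: np.ndarray, t: int, att: AttentionParams) -> np.ndarray:
    """Attention-pooling vector c_t for position t (0-based)."""
    return attention_weights(V, t, att) @ np.asarray(V, dtype=np.float64)


def self_match_encode(V: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Self-matching layer output H (m, 2k) for one unpadded sentence."""
    Vt = Tensor(np.asarray(V, dtype=np.float64)[None])
    return self_match_batch(Vt, params, _full_mask(V.shape[0])).data[0]


def context_encode(H: np.ndarray, params: EncoderParams) -> np.ndarray:
    """Context layer output L (m, 2k) for one unpadded sentence."""
    Ht = Tensor(np.asarray(H, dtype=np.float64)[None])
    return context_batch(Ht, params, _full_mask(H.shape[0])).data[0]


def project_emissions(L: np.ndarray, W_p: np.ndarray, b_p: np.ndarray) -> np.ndarray:
    """Linear projection of context features to emission scores L W_p + b_p."""
    L = np.asarray(L, dtype=np.float64)
    W_p = np.asarray(W_p, dtype=np.float64)
    b_p = np.asarray(b_p, dtype=np.float64)
    if L.shape[-1] != W_p.shape[0] or W_p.shape[1] != b_p.shape[0]:
        raise ValueError(
            f"shape mismatch: L {L.shape}, W_p {W_p.shape}, b_p {b_p.shape}"
        )
    return L @ W_p + b_p
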