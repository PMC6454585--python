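"""Linear-chain conditional random field.

Scores a tag sequence y over an m-character sentence as

    s(V, y) = sum_{i=0..m} A[y_i, y_{i+1}] + sum_{i=1..m} P[i, y_i]

with virtual start (y_0) and end (y_{m+1}) states, emission matrix P from
the encoder and a learned (n+2) x (n+2) transition matrix A.  The sequence
probability is the globally normalized softmax over all n^m tag sequences;
the partition function is computed exactly by the forward algorithm in
O(m n^2) with log-sum-exp stabilization, and decoding is exact Viterbi.

Transitions into the start state and out of the end state are structurally
impossible; in exported potentials those cells are -inf, and none of the
algorithms ever reads them (they index only the n x n interior block plus
the start row and end column).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp as np_logsumexp

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "CRFPotentials",
    "score_sequence",
    "log_partition",
    "nll_loss",
    "viterbi_decode",
    "crf_nll_batch",
    "bio_transition_mask",
]


@dataclass
class CRFPotentials:
    """Emission and transition potentials for one sentence.

    ``emissions`` is m x n; ``transitions`` is (n+2) x (n+2) where index n is
    the virtual start state and index n+1 the virtual end state.
    """

    emissions: np.ndarray
    transitions: np.ndarray

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=np.float64)
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        m, n = self.emissions.shape
        if self.transitions.shape != (n + 2, n + 2):
            raise ValueError(
                f"transitions must be ({n + 2}, {n + 2}) for {n} labels, "
                f"got {self.transitions.shape}"
            )
        if m < 1:
            raise ValueError("emissions must cover at least one position")
        if not np.all(np.isfinite(self.emissions)):
            raise ValueError("emissions must be finite")

    @property
    def m(self) -> int:
        return self.emissions.shape[0]

    @property
    def n(self) -> int:
        return self.emissions.shape[1]

    @property
    def start(self) -> int:
        return self.n

    @property
    def end(self) -> int:
        return self.n + 1


def _check_tags(pot: CRFPotentials, y: Sequence[int]) -> np.ndarray:
    y = np.asarray(y, dtype=np.intp)
    if y.shape != (pot.m,):
        raise ValueError(f"tag sequence must have length {pot.m}, got {y.shape}")
    if y.size and (y.min() < 0 or y.max() >= pot.n):
        raise IndexError(f"tag indices must lie in [0, {pot.n})")
    return y


def score_sequence(pot: CRFPotentials, y: Sequence[int]) -> float:
    """Unnormalized score of one tag sequence, boundary transitions included.

    Accumulated in the same transition-then-emission order as the forward
    recursion so that single-path instances (n = 1) cancel exactly in the
    loss.
    """
    y = _check_tags(pot, y)
    A, E = pot.transitions, pot.emissions
    s = A[pot.start, y[0]] + E[0, y[0]]
    for t in range(1, pot.m):
        s = (s + A[y[t - 1], y[t]]) + E[t, y[t]]
    return float(s + A[y[-1], pot.end])


def log_partition(pot: CRFPotentials) -> float:
    """log sum over all n^m tag sequences of exp(score), by the forward
    algorithm."""
    A, E = pot.transitions, pot.emissions
    n = pot.n
    alpha = A[pot.start, :n] + E[0]
    inner = A[:n, :n]
    for t in range(1, pot.m):
        alpha = np_logsumexp(alpha[:, None] + inner, axis=0) + E[t]
    out = float(np_logsumexp(alpha + A[:n, pot.end]))
    if not np.isfinite(out):
        raise FloatingPointError("log partition is not finite")
    return out


def nll_loss(pot: CRFPotentials, y_gold: Sequence[int]) -> float:
    """Negative log-likelihood -log p(y_gold | V); always >= 0."""
    return log_partition(pot) - score_sequence(pot, y_gold)


def viterbi_decode(pot: CRFPotentials) -> tuple[list[int], float]:
    """Exact argmax tag sequence and its score.

    Ties are broken toward the lowest label index at every backtrack step
    (``argmax`` returns the first maximizer), so decoding is deterministic.
    """
    A, E = pot.transitions, pot.emissions
    n, m = pot.n, pot.m
    delta = A[pot.start, :n] + E[0]
    back = np.zeros((m, n), dtype=np.intp)
    inner = A[:n, :n]
    for t in range(1, m):
        scores = delta[:, None] + inner  # [prev, next]
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(n)] + E[t]
    final = delta + A[:n, pot.end]
    last = int(np.argmax(final))
    path = [last]
    for t in range(m - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, float(final[last])


# ---------------------------------------------------------------------------
# differentiable batched loss (training path)
# ---------------------------------------------------------------------------

def crf_nll_batch(
    emissions: Tensor,
    transitions: Tensor,
    tags: np.ndarray,
    mask: np.ndarray,
) -> Tensor:
    """Mean per-sentence negative log-likelihood over a padded batch.

    Parameters
    ----------
    emissions : Tensor, shape (B, m, n)
    transitions : Tensor, shape (n+2, n+2), start index n, end index n+1
    tags : int array (B, m), arbitrary values at padded positions
    mask : float array (B, m), 1 at real positions; every sentence must have
        mask[:, 0] == 1 (no empty sentences).
    """
    B, m, n = emissions.shape
    start, end = n, n + 1
    inner = transitions[:n, :n]
    from_start = transitions[start, :n]
    to_end = transitions[:n, end]

    # forward algorithm
    alpha = emissions[:, 0, :] + ag.expand_dims(from_start, 0)
    for t in range(1, m):
        prev = ag.expand_dims(alpha, 2)          # (B, n, 1)
        step = ag.logsumexp(prev + ag.expand_dims(inner, 0), axis=1)
        nxt = step + emissions[:, t, :]
        mt = mask[:, t:t + 1]
        alpha = Tensor(mt) * nxt + Tensor(1.0 - mt) * alpha
    log_z = ag.logsumexp(alpha + ag.expand_dims(to_end, 0), axis=1)  # (B,)

    # gold-path score
    b_idx = np.arange(B)[:, None]
    t_idx = np.arange(m)[None, :]
    emit = emissions[(b_idx, t_idx, tags)]                 # (B, m)
    emit_score = ag.tsum(emit * Tensor(mask), axis=1)
    score = from_start[tags[:, 0]] + emit_score
    if m > 1:
        trans = transitions[(tags[:, :-1], tags[:, 1:])]   # (B, m-1)
        score = score + ag.tsum(trans * Tensor(mask[:, 1:]), axis=1)
    lengths = mask.sum(axis=1).astype(np.intp)
    last_tags = tags[np.arange(B), lengths - 1]
    score = score + to_end[last_tags]

    return ag.tsum(log_z - score) * (1.0 / B)


def bio_transition_mask(n_labels: int, scheme=None) -> np.ndarray:
    """Additive penalty matrix forbidding illegal BIO bigrams (optional mode).

    Returns an (n+2, n+2) array of 0 / -1e4: an ``I_c`` may only follow
    ``B_c`` or ``I_c``.  Off by default; the plain model learns transitions.
    """
    from .corpus_io import LabelScheme

    scheme = scheme or LabelScheme()
    if scheme.n_labels != n_labels:
        raise ValueError("scheme size does not match n_labels")
    penalty = np.zeros((n_labels + 2, n_labels + 2))
    start = n_labels
    for j, label in enumerate(scheme.labels):
        prefix, cat = scheme.parse(label)
        if prefix != "I":
            continue
        for i, prev in enumerate(scheme.labels):
            p_prefix, p_cat = scheme.parse(prev)
            if p_cat != cat:
                penalty[i, j] = -1e4
        penalty[start, j] = -1e4
    return penalty
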