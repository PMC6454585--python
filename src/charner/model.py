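"""The character-level tagger: encoder + CRF, vocabularies, fit/predict.

Input modes
-----------
``char``
    Character embeddings only.
``char+pos``
    Characters concatenated with embeddings of plain word-to-character
    projected POS tags.
``char+reduced_pos``
    Characters concatenated with embeddings of reduced POS tags (general
    dictionary built from the training split only; out-of-dictionary
    segments collapse to the reserved tag "s").

The mode only changes which POS column the corpus carries; the model simply
embeds whatever POS strings it is given, so the two POS modes share all
machinery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Adam, Tensor
from .corpus_io import AnnotatedSentence, LabelScheme
from .crf import CRFPotentials, bio_transition_mask, crf_nll_batch, viterbi_decode
from .encoder import (
    AttentionParams,
    EncoderParams,
    LSTMParams,
    encode_inputs,
    init_encoder_params,
)

__all__ = ["TrainConfig", "SelfMatchingTagger", "TrainingDivergedError"]

PAD, UNK = 0, 1
INPUT_MODES = ("char", "char+pos", "char+reduced_pos")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss stops being finite."""


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the reference setting:
    50-dim character and POS embeddings, Adam at 0.001, batch 32, at most 20
    epochs, 200 hidden units, early stop on an epoch-loss delta of 0.001)."""

    input_mode: str = "char+reduced_pos"
    char_embedding_size: int = 50
    pos_embedding_size: int = 50
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 20
    hidden_units: int = 200
    attention_dim: int | None = None
    early_stop_delta: float = 0.001
    dropout: float = 0.0
    transition_bio_mask: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        for name in ("char_embedding_size", "pos_embedding_size", "learning_rate",
                     "batch_size", "max_epochs", "hidden_units"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def uses_pos(self) -> bool:
        return self.input_mode != "char"


def _build_vocab(items: Sequence[str]) -> dict[str, int]:
    """Frequency-then-lexicographic vocabulary; 0 = padding, 1 = unknown."""
    counts: dict[str, int] = {}
    for it in items:
        counts[it] = counts.get(it, 0) + 1
    ordered = sorted(counts, key=lambda w: (-counts[w], w))
    return {w: i + 2 for i, w in enumerate(ordered)}


class SelfMatchingTagger:
    """Self-matching attention BiLSTM-CRF tagger over characters."""

    def __init__(self, config: TrainConfig, scheme: LabelScheme,
                 char_vocab: dict[str, int], pos_vocab: dict[str, int] | None,
                 params: EncoderParams, transitions: Tensor):
        self.config = config
        self.scheme = scheme
        self.char_vocab = char_vocab
        self.pos_vocab = pos_vocab
        self.params = params
        self.transitions = transitions
        n = scheme.n_labels
        self._trans_penalty = (
            bio_transition_mask(n, scheme) if config.transition_bio_mask else None
        )

    # -- construction --------------------------------------------------
    @classmethod
    def build(cls, config: TrainConfig, train_corpus: Sequence[AnnotatedSentence],
              scheme: LabelScheme | None = None) -> "SelfMatchingTagger":
        """Initialize a model whose vocabularies come from the training
        split only."""
        if not train_corpus:
            raise ValueError("cannot build a model from an empty corpus")
        scheme = scheme or LabelScheme()
        char_vocab = _build_vocab([c for s in train_corpus for c in s.chars])
        pos_vocab = None
        if config.uses_pos:
            tags = [p for s in train_corpus if s.pos for p in s.pos]
            if not tags:
                raise ValueError(
                    f"input_mode {config.input_mode!r} needs a POS column on "
                    "the training corpus (see pos_preprocess.apply_pos_tagging)"
                )
            pos_vocab = _build_vocab(tags)
        rng = np.random.default_rng(config.seed)
        n = scheme.n_labels
        params = init_encoder_params(
            rng,
            n_chars=len(char_vocab) + 2,
            n_pos=(len(pos_vocab) + 2) if pos_vocab else None,
            n_labels=n,
            emb_dim=config.char_embedding_size,
            hidden=config.hidden_units,
            att_dim=config.attention_dim,
        )
        transitions = Tensor(
            rng.uniform(-0.1, 0.1, size=(n + 2, n + 2)), requires_grad=True
        )
        return cls(config, scheme, char_vocab, pos_vocab, params, transitions)

    # -- encoding helpers ----------------------------------------------
    def _ids(self, sent: AnnotatedSentence) -> tuple[np.ndarray, np.ndarray | None]:
        chars = np.array([self.char_vocab.get(c, UNK) for c in sent.chars],
                         dtype=np.intp)
        pos = None
        if self.config.uses_pos:
            if sent.pos is None:
                raise ValueError(
                    f"sentence {sent.text!r} lacks the POS column required by "
                    f"input_mode {self.config.input_mode!r}"
                )
            pos = np.array([self.pos_vocab.get(p, UNK) for p in sent.pos],
                           dtype=np.intp)
        return chars, pos

    def _batch_arrays(self, batch: Sequence[AnnotatedSentence]):
        B = len(batch)
        m = max(len(s) for s in batch)
        char_ids = np.zeros((B, m), dtype=np.intp)
        pos_ids = np.zeros((B, m), dtype=np.intp) if self.config.uses_pos else None
        mask = np.zeros((B, m))
        tags = np.zeros((B, m), dtype=np.intp)
        for i, sent in enumerate(batch):
            c, p = self._ids(sent)
            L = len(sent)
            char_ids[i, :L] = c
            if pos_ids is not None:
                pos_ids[i, :L] = p
            mask[i, :L] = 1.0
            if sent.labels is not None:
                tags[i, :L] = [self.scheme.label_to_index[l] for l in sent.labels]
        return char_ids, pos_ids, mask, tags

    def _input_rows(self, char_ids, pos_ids, params: EncoderParams,
                    dropout_rng: np.random.Generator | None = None) -> Tensor:
        V = params.char_emb[char_ids]
        if pos_ids is not None:
            V = ag.concatenate([V, params.pos_emb[pos_ids]], axis=2)
        p = self.config.dropout
        if dropout_rng is not None and p > 0.0:
            keep = dropout_rng.random(V.shape) >= p
            V = V * Tensor(keep / (1.0 - p))
        return V

    def _emissions(self, batch, params: EncoderParams, transitions: Tensor,
                   dropout_rng=None):
        char_ids, pos_ids, mask, tags = self._batch_arrays(batch)
        V = self._input_rows(char_ids, pos_ids, params, dropout_rng)
        emissions = encode_inputs(V, params, mask)
        return emissions, transitions, mask, tags

    def loss_batch(self, batch: Sequence[AnnotatedSentence],
                   dropout_rng: np.random.Generator | None = None) -> Tensor:
        """Mean CRF negative log-likelihood of a batch (builds the training
        graph)."""
        emissions, transitions, mask, tags = self._emissions(
            batch, self.params, self.transitions, dropout_rng
        )
        if self._trans_penalty is not None:
            transitions = transitions + Tensor(self._trans_penalty)
        return crf_nll_batch(emissions, transitions, tags, mask)

    # -- training ------------------------------------------------------
    def fit(self, train_corpus: Sequence[AnnotatedSentence],
            verbose: bool = False) -> list[float]:
        """Train with Adam; returns the per-epoch mean sentence loss trace.

        Stops early once two consecutive epoch losses differ by no more than
        ``early_stop_delta``; otherwise runs ``max_epochs`` epochs.  Fully
        reproducible for a fixed config seed.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        optim = Adam(self.params.tensors() + [self.transitions],
                     lr=cfg.learning_rate)
        # length-sorted static batches; epoch shuffling permutes batch order
        order = sorted(range(len(train_corpus)),
                       key=lambda i: (len(train_corpus[i]), i))
        batches = [
            [train_corpus[j] for j in order[i:i + cfg.batch_size]]
            for i in range(0, len(order), cfg.batch_size)
        ]
        trace: list[float] = []
        for epoch in range(1, cfg.max_epochs + 1):
            total, count = 0.0, 0
            for bi in rng.permutation(len(batches)):
                batch = batches[bi]
                optim.zero_grad()
                loss = self.loss_batch(batch, dropout_rng=rng)
                value = loss.item()
                if not np.isfinite(value):
                    raise TrainingDivergedError(
                        f"non-finite loss {value} in epoch {epoch} "
                        f"(batch of {len(batch)} sentences, lr={cfg.learning_rate})"
                    )
                loss.backward()
                optim.step()
                total += value * len(batch)
                count += len(batch)
            trace.append(total / count)
            if verbose:
                print(f"epoch {epoch:2d}  mean CRF loss {trace[-1]:.4f}")
            if epoch >= 2 and abs(trace[-1] - trace[-2]) <= cfg.early_stop_delta:
                break
        return trace

    # -- inference -----------------------------------------------------
    def _frozen_params(self) -> tuple[EncoderParams, Tensor]:
        """Detach parameters so prediction builds no autograd graph."""
        t = lambda x: Tensor(x.data) if x is not None else None
        p = self.params
        frozen = EncoderParams(
            char_emb=t(p.char_emb), pos_emb=t(p.pos_emb),
            att=AttentionParams(t(p.att.w), t(p.att.W_v), t(p.att.W_vhat)),
            fwd=LSTMParams(t(p.fwd.W), t(p.fwd.b)),
            bwd=LSTMParams(t(p.bwd.W), t(p.bwd.b)),
            ctx_fwd=LSTMParams(t(p.ctx_fwd.W), t(p.ctx_fwd.b)),
            ctx_bwd=LSTMParams(t(p.ctx_bwd.W), t(p.ctx_bwd.b)),
            W_p=t(p.W_p), b_p=t(p.b_p),
        )
        return frozen, Tensor(self.transitions.data)

    def potentials(self, sentence: AnnotatedSentence) -> CRFPotentials:
        """Exported CRF potentials for one sentence (structurally impossible
        transitions set to -inf)."""
        params, transitions = self._frozen_params()
        emissions, _, mask, _ = self._emissions([sentence], params, transitions)
        A = transitions.data.copy()
        if self._trans_penalty is not None:
            A = A + self._trans_penalty
        n = self.scheme.n_labels
        A[:, n] = -np.inf      # nothing enters start
        A[n + 1, :] = -np.inf  # nothing leaves end
        return CRFPotentials(emissions=emissions.data[0], transitions=A)

    def predict(self, sentences: Sequence[AnnotatedSentence],
                batch_size: int | None = None) -> list[list[str]]:
        """Viterbi-decode BIO label sequences; unknown symbols map to the
        reserved unknown index, never an error."""
        if not sentences:
            return []
        bs = batch_size or self.config.batch_size
        params, transitions = self._frozen_params()
        A = transitions.data.copy()
        if self._trans_penalty is not None:
            A = A + self._trans_penalty
        n = self.scheme.n_labels
        A[:, n] = -np.inf
        A[n + 1, :] = -np.inf
        out: list[list[str]] = []
        for i in range(0, len(sentences), bs):
            batch = list(sentences[i:i + bs])
            emissions, _, mask, _ = self._emissions(batch, params, transitions)
            for j, sent in enumerate(batch):
                L = len(sent)
                pot = CRFPotentials(emissions=emissions.data[j, :L], transitions=A)
                path, _ = viterbi_decode(pot)
                out.append([self.scheme.index_to_label[k] for k in path])
        return out

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: one .npz of arrays plus a JSON sidecar with config,
        label scheme and vocabularies."""
        path = Path(path)
        arrays = {f"p{i}": t.data for i, t in enumerate(self.params.tensors())}
        arrays["transitions"] = self.transitions.data
        np.savez(path, **arrays)
        sidecar = {
            "config": asdict(self.config),
            "categories": [(name, self.scheme._code[name])
                           for name in self.scheme.categories],
            "char_vocab": self.char_vocab,
            "pos_vocab": self.pos_vocab,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path) -> "SelfMatchingTagger":
        path = Path(path)
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".json").read_text(encoding="utf-8")
        )
        config = TrainConfig(**sidecar["config"])
        scheme = LabelScheme([tuple(c) for c in sidecar["categories"]])
        char_vocab = sidecar["char_vocab"]
        pos_vocab = sidecar["pos_vocab"]
        rng = np.random.default_rng(config.seed)
        params = init_encoder_params(
            rng,
            n_chars=len(char_vocab) + 2,
            n_pos=(len(pos_vocab) + 2) if pos_vocab else None,
            n_labels=scheme.n_labels,
            emb_dim=config.char_embedding_size,
            hidden=config.hidden_units,
            att_dim=config.attention_dim,
        )
        with np.load(path) as data:
            for i, t in enumerate(params.tensors()):
                t.data = data[f"p{i}"]
            transitions = Tensor(data["transitions"], requires_grad=True)
        return cls(config, scheme, char_vocab, pos_vocab, params, transitions)
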