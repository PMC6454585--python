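"""Training orchestration and strict entity-level evaluation.

Scoring is strict: a predicted entity counts as a true positive only when
its category and its exact character boundaries both match a gold entity,
and each gold entity can be matched at most once.  Precision, recall and F1
follow the usual micro-averaged definitions; per-category tables, an error
taxonomy (boundary/category confusion of overlapping errors) and a
length-stratified histogram of correct entities support the boundary
analyses.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import AnnotatedSentence, EntitySpan, labels_to_spans
from .model import SelfMatchingTagger, TrainConfig, TrainingDivergedError

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "LENGTH_BINS",
    "train",
    "predict",
    "predict_spans",
    "evaluate",
    "classify_errors",
    "length_stratified_counts",
]

#: Gold entity length bins (characters) for the correct-entity histogram.
LENGTH_BINS: tuple[tuple[int, float], ...] = (
    (1, 5), (6, 10), (11, 15), (16, float("inf")),
)
BIN_NAMES = ("1-5", "6-10", "11-15", ">15")


@dataclass
class TrainResult:
    model: SelfMatchingTagger
    loss_trace: list[float]
    seconds: float

    @property
    def stopped_epoch(self) -> int:
        return len(self.loss_trace)


def train(config: TrainConfig, train_corpus: Sequence[AnnotatedSentence],
          dev_corpus: Sequence[AnnotatedSentence] | None = None,
          verbose: bool = False) -> TrainResult:
    """Build and fit a tagger on the training split.

    Early stopping triggers when the mean per-sentence CRF loss of two
    consecutive epochs differs by at most ``config.early_stop_delta``;
    otherwise training runs for ``config.max_epochs`` epochs.  ``dev_corpus``
    is accepted for API symmetry but unused: the stopping rule needs no held
    -out data.
    """
    if not train_corpus:
        raise ValueError("training corpus is empty")
    model = SelfMatchingTagger.build(config, train_corpus)
    t0 = time.perf_counter()
    trace = model.fit(train_corpus, verbose=verbose)
    return TrainResult(model=model, loss_trace=trace,
                       seconds=time.perf_counter() - t0)


def predict(model: SelfMatchingTagger,
            sentences: Sequence[AnnotatedSentence],
            batch_size: int | None = None) -> list[list[str]]:
    """BIO label sequences for ``sentences`` (one list per sentence)."""
    return model.predict(sentences, batch_size=batch_size)


def predict_spans(model: SelfMatchingTagger,
                  sentences: Sequence[AnnotatedSentence],
                  batch_size: int | None = None) -> list[list[EntitySpan]]:
    """Predicted entity spans after BIO repair, one list per sentence."""
    return [labels_to_spans(labels, model.scheme)
            for labels in predict(model, sentences, batch_size=batch_size)]


# ---------------------------------------------------------------------------
# strict entity-level scoring
# ---------------------------------------------------------------------------

def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class EvalReport:
    """Strict micro-averaged scores plus the boundary analyses."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    per_category: dict[str, dict[str, float]]
    error_taxonomy: dict[str, int]
    spurious: int
    length_histogram: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "per_category": self.per_category,
            "error_taxonomy": self.error_taxonomy,
            "spurious": self.spurious,
            "length_histogram": self.length_histogram,
        }


def _check_aligned(gold, pred) -> None:
    if len(gold) != len(pred):
        raise ValueError(
            f"gold has {len(gold)} sentences but pred has {len(pred)}"
        )


def _match(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]):
    """Exact matching within one sentence; each gold span used at most once."""
    gold_left = set(gold)
    tp_spans, err_spans = [], []
    for span in pred:
        if span in gold_left:
            gold_left.discard(span)
            tp_spans.append(span)
        else:
            err_spans.append(span)
    return tp_spans, err_spans, gold_left


def evaluate(gold: Sequence[Sequence[EntitySpan]],
             pred: Sequence[Sequence[EntitySpan]]) -> EvalReport:
    """Strict entity-level evaluation over aligned per-sentence span lists."""
    _check_aligned(gold, pred)
    cats: dict[str, dict[str, int]] = {}

    def bucket(cat: str) -> dict[str, int]:
        return cats.setdefault(cat, {"tp": 0, "fp": 0, "fn": 0})

    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        tp_spans, err_spans, missed = _match(g, p)
        tp += len(tp_spans)
        fp += len(err_spans)
        fn += len(missed)
        for s in tp_spans:
            bucket(s.category)["tp"] += 1
        for s in err_spans:
            bucket(s.category)["fp"] += 1
        for s in missed:
            bucket(s.category)["fn"] += 1
    precision, recall, f1 = _prf(tp, fp, fn)
    per_category = {}
    for cat, c in sorted(cats.items()):
        cp, cr, cf = _prf(c["tp"], c["fp"], c["fn"])
        per_category[cat] = {**c, "precision": cp, "recall": cr, "f1": cf}
    taxonomy, spurious = classify_errors(gold, pred)
    return EvalReport(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1,
        per_category=per_category,
        error_taxonomy=taxonomy,
        spurious=spurious,
        length_histogram=length_stratified_counts(gold, pred),
    )


def classify_errors(gold: Sequence[Sequence[EntitySpan]],
                    pred: Sequence[Sequence[EntitySpan]]) -> tuple[dict[str, int], int]:
    """Boundary/category taxonomy of erroneous predictions.

    Every non-TP predicted span overlapping at least one gold span is
    classified against the maximally overlapping gold span (ties broken to
    the earliest-starting, then longest gold span) into:

    - ``correct_boundary_wrong_category``
    - ``wrong_boundary_correct_category``
    - ``wrong_boundary_wrong_category``

    Predictions overlapping no gold span are returned separately as the
    spurious count, so taxonomy + TP + spurious = total predictions.
    """
    _check_aligned(gold, pred)
    taxonomy = {
        "correct_boundary_wrong_category": 0,
        "wrong_boundary_correct_category": 0,
        "wrong_boundary_wrong_category": 0,
    }
    spurious = 0
    for g, p in zip(gold, pred):
        _, err_spans, _ = _match(g, p)
        for span in err_spans:
            overlapping = [gs for gs in g if gs.overlaps(span)]
            if not overlapping:
                spurious += 1
                continue
            best = max(
                overlapping,
                key=lambda gs: (
                    min(gs.end, span.end) - max(gs.start, span.start),
                    -gs.start,
                    len(gs),
                ),
            )
            boundary_ok = (best.start, best.end) == (span.start, span.end)
            category_ok = best.category == span.category
            if boundary_ok and not category_ok:
                taxonomy["correct_boundary_wrong_category"] += 1
            elif category_ok:
                taxonomy["wrong_boundary_correct_category"] += 1
            else:
                taxonomy["wrong_boundary_wrong_category"] += 1
    return taxonomy, spurious


def length_stratified_counts(gold: Sequence[Sequence[EntitySpan]],
                             pred: Sequence[Sequence[EntitySpan]]) -> dict[str, dict[str, int]]:
    """Correct-entity counts binned by gold entity length (1-5 / 6-10 /
    11-15 / >15 characters), alongside the gold totals per bin."""
    _check_aligned(gold, pred)
    hist = {name: {"correct": 0, "gold": 0} for name in BIN_NAMES}

    def bin_name(length: int) -> str:
        for (lo, hi), name in zip(LENGTH_BINS, BIN_NAMES):
            if lo <= length <= hi:
                return name
        raise AssertionError(f"length {length} fell through the bins")

    for g, p in zip(gold, pred):
        tp_spans, _, _ = _match(g, p)
        for span in g:
            hist[bin_name(len(span))]["gold"] += 1
        for span in tp_spans:
            hist[bin_name(len(span))]["correct"] += 1
    return hist
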