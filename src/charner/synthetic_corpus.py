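"""Synthetic annotated corpora with the structure the tagger assumes.

Real clinical admission notes cannot be redistributed, so every pipeline
stage is exercised on generated corpora that copy the *statistical shape* of
that data: five entity categories whose mean lengths differ strongly
(defaults 2.5 / 1.5 / 2.5 / 3.4 / 7.9 characters, with category frequencies
matching the reference training split), entities embedded between ordinary
context words, occasional Chinese punctuation, and — crucially — a long
category whose surface forms are built from two sub-words that the toy
segmenter knows individually, so word segmentation cuts long entities into
differently-tagged pieces (the failure mode reduced POS tagging targets).

Characters are drawn from disjoint CJK code-point blocks per role; the text
is not meaningful Chinese, only structurally analogous.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import poisson

from .corpus_io import (
    AnnotatedSentence,
    EntitySpan,
    LabelScheme,
    labels_to_spans,
    spans_to_labels,
    write_corpus,
)
from .pos_preprocess import ToySegmenter

__all__ = [
    "DEFAULT_MEAN_LENGTHS",
    "DEFAULT_CATEGORY_WEIGHTS",
    "CorpusSpec",
    "CorpusBundle",
    "generate_corpus",
    "corpus_statistics",
    "easy_corpus_spec",
    "hard_corpus_spec",
    "write_bundle",
]

#: Mean entity length (characters) per category in the reference train split.
DEFAULT_MEAN_LENGTHS: dict[str, float] = {
    "AnatomicalPart": 2.5,
    "SymptomDescription": 1.5,
    "IndependentSymptoms": 2.5,
    "Drug": 3.4,
    "Operation": 7.9,
}

#: Entity counts per category in the reference train split, used as
#: relative sampling weights.
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "AnatomicalPart": 7838,
    "SymptomDescription": 2066,
    "IndependentSymptoms": 3055,
    "Drug": 1005,
    "Operation": 1116,
}

# disjoint CJK code-point blocks
_CONTEXT_BLOCK = (0x4E00, 160)
_CATEGORY_BLOCKS = {
    "AnatomicalPart": (0x5100, 48),
    "SymptomDescription": (0x5200, 48),
    "IndependentSymptoms": (0x5300, 48),
    "Drug": (0x5400, 48),
    "Operation": (0x5500, 48),
}
_UNKNOWN_BLOCK = (0x6800, 48)

_PUNCTUATION = "，。；、"
_CONTEXT_POS = ("n", "v", "d", "p", "a")
_CONTEXT_POS_W = (0.35, 0.25, 0.15, 0.15, 0.10)


@dataclass
class CorpusSpec:
    """Stated world of one generated corpus; fully determined by ``seed``."""

    n_sentences: int = 600
    category_mean_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_LENGTHS))
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))
    entities_per_sentence_mean: float = 1.2
    max_entities_per_sentence: int = 3
    context_vocab_size: int = 80
    lexicon_size: int = 40
    punctuation_prob: float = 0.15
    #: draw entity characters from the context block instead of per-category
    #: blocks (removes the trivial character-identity cue)
    shared_alphabet: bool = False
    #: categories whose surfaces are two segmenter-known pieces (POS n + v)
    split_long_categories: tuple[str, ...] = ("Operation",)
    #: categories sampled fresh per occurrence from a disjoint alphabet
    #: (exercises unknown-character handling)
    open_vocab_categories: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be positive")
        if self.lexicon_size < 1 or self.context_vocab_size < 1:
            raise ValueError("lexicons must be non-empty")
        if self.entities_per_sentence_mean < 0:
            raise ValueError("entities_per_sentence_mean must be >= 0")
        for cat, mean in self.category_mean_lengths.items():
            floor = 2.0 if cat in self.split_long_categories else 1.0
            if mean < floor:
                raise ValueError(f"mean length {mean} too small for {cat}")


@dataclass
class CorpusBundle:
    """A generated corpus: sentences with gold labels, the matching span
    lists, and the toy-segmenter lexicon that reproduces the intended
    (mis)segmentation."""

    sentences: list[AnnotatedSentence]
    spans: list[list[EntitySpan]]
    segmenter_lexicon: dict[str, str]
    spec: CorpusSpec

    @property
    def segmenter(self) -> ToySegmenter:
        return ToySegmenter(self.segmenter_lexicon)


def _stratified_lengths(mean: float, n: int, shift: int,
                        rng: np.random.Generator) -> list[int]:
    """n integer lengths >= shift with empirical mean ~ ``mean``.

    Lengths are ``shift`` plus Poisson(mean - shift) quantiles taken at
    stratified probabilities, so the lexicon realizes the target length
    distribution faithfully even at small n.
    """
    mu = mean - shift
    qs = (np.arange(n) + 0.5) / n
    lengths = shift + poisson.ppf(qs, mu).astype(int)
    rng.shuffle(lengths)
    return [int(x) for x in lengths]


def _word(rng: np.random.Generator, alphabet: Sequence[str], length: int,
          taken: set[str]) -> str:
    for _ in range(1000):
        w = "".join(rng.choice(alphabet, size=length))
        if w not in taken:
            taken.add(w)
            return w
    raise RuntimeError("alphabet exhausted while drawing unique words")


def _alphabet(block: tuple[int, int]) -> list[str]:
    start, size = block
    return [chr(start + i) for i in range(size)]


def generate_corpus(spec: CorpusSpec) -> CorpusBundle:
    """Generate a corpus, its gold spans and the matching segmenter lexicon.

    Sentences alternate context chunks (1-2 ordinary words) and entity
    surface forms; punctuation is inserted between chunks with
    ``spec.punctuation_prob``.  Split-category surfaces are piece1 + piece2
    with the pieces (not the whole) in the segmenter lexicon, tagged n and v
    respectively, so the segmenter cuts them apart.  Byte-identical across
    runs for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = LabelScheme()
    categories = list(spec.category_mean_lengths)
    for cat in categories:
        if cat not in scheme.categories:
            raise ValueError(f"unknown category {cat!r}")

    context_alpha = _alphabet(_CONTEXT_BLOCK)
    unknown_alpha = _alphabet(_UNKNOWN_BLOCK)
    taken: set[str] = set()

    # ordinary-word context lexicon
    context_words: list[tuple[str, str]] = []
    ctx_lengths = _stratified_lengths(1.9, spec.context_vocab_size, 1, rng)
    for length in ctx_lengths:
        w = _word(rng, context_alpha, min(length, 3), taken)
        pos = rng.choice(_CONTEXT_POS, p=_CONTEXT_POS_W)
        context_words.append((w, str(pos)))

    segmenter_lexicon: dict[str, str] = {w: p for w, p in context_words}
    for ch in _PUNCTUATION:
        segmenter_lexicon[ch] = "w"

    # per-category entity lexicons
    entity_lexicons: dict[str, list[str]] = {}
    for cat in categories:
        mean = spec.category_mean_lengths[cat]
        if cat in spec.open_vocab_categories:
            entity_lexicons[cat] = []  # sampled per occurrence
            continue
        alpha = (context_alpha if spec.shared_alphabet
                 else _alphabet(_CATEGORY_BLOCKS[cat]))
        forms: list[str] = []
        if cat in spec.split_long_categories:
            for total in _stratified_lengths(mean, spec.lexicon_size, 2, rng):
                left = max(1, total // 2)
                piece1 = _word(rng, alpha, left, taken)
                piece2 = _word(rng, alpha, total - left, taken)
                segmenter_lexicon[piece1] = "n"
                segmenter_lexicon[piece2] = "v"
                forms.append(piece1 + piece2)
        else:
            for length in _stratified_lengths(mean, spec.lexicon_size, 1, rng):
                forms.append(_word(rng, alpha, length, taken))
        entity_lexicons[cat] = forms

    weights = np.array([spec.category_weights.get(c, 1.0) for c in categories],
                       dtype=float)
    weights = weights / weights.sum()

    def draw_entity(cat: str) -> str:
        if cat in spec.open_vocab_categories:
            mean = spec.category_mean_lengths[cat]
            length = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
            return "".join(rng.choice(unknown_alpha, size=length))
        forms = entity_lexicons[cat]
        return forms[int(rng.integers(len(forms)))]

    def context_chunk() -> str:
        n_words = int(rng.integers(1, 3))
        chunk = "".join(
            context_words[int(rng.integers(len(context_words)))][0]
            for _ in range(n_words)
        )
        if rng.random() < spec.punctuation_prob:
            chunk += str(rng.choice(list(_PUNCTUATION)))
        return chunk

    sentences: list[AnnotatedSentence] = []
    all_spans: list[list[EntitySpan]] = []
    for _ in range(spec.n_sentences):
        n_ent = min(int(rng.poisson(spec.entities_per_sentence_mean)),
                    spec.max_entities_per_sentence)
        text = context_chunk()
        spans: list[EntitySpan] = []
        for _ in range(n_ent):
            cat = categories[int(rng.choice(len(categories), p=weights))]
            surface = draw_entity(cat)
            spans.append(EntitySpan(cat, len(text), len(text) + len(surface)))
            text += surface
            text += context_chunk()
        labels = spans_to_labels(spans, len(text), scheme)
        sentences.append(AnnotatedSentence(chars=list(text), labels=labels))
        all_spans.append(spans)

    return CorpusBundle(sentences=sentences, spans=all_spans,
                        segmenter_lexicon=segmenter_lexicon, spec=spec)


def corpus_statistics(sentences: Sequence[AnnotatedSentence],
                      scheme: LabelScheme | None = None) -> dict[str, dict[str, float]]:
    """Per-category entity counts and mean character lengths, from labels."""
    scheme = scheme or LabelScheme()
    counts: dict[str, int] = {}
    total_len: dict[str, int] = {}
    for sent in sentences:
        if sent.labels is None:
            raise ValueError("corpus statistics require gold labels")
        for span in labels_to_spans(sent.labels, scheme):
            counts[span.category] = counts.get(span.category, 0) + 1
            total_len[span.category] = total_len.get(span.category, 0) + len(span)
    return {
        cat: {"count": counts[cat], "mean_length": total_len[cat] / counts[cat]}
        for cat in sorted(counts)
    }


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def easy_corpus_spec(seed: int, n_sentences: int = 600) -> CorpusSpec:
    """Learnable-by-design world: closed per-category lexicons over disjoint
    character blocks, reference category frequencies and mean lengths."""
    return CorpusSpec(n_sentences=n_sentences, seed=seed)


def hard_corpus_spec(seed: int, n_sentences: int = 600) -> CorpusSpec:
    """Boundary-stress world: entity characters share the context alphabet
    (no character-identity shortcut) and categories are sampled uniformly so
    the long split category is frequent enough to compare input modes on."""
    return CorpusSpec(
        n_sentences=n_sentences,
        category_weights={c: 1.0 for c in DEFAULT_MEAN_LENGTHS},
        shared_alphabet=True,
        entities_per_sentence_mean=1.5,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_bundle(bundle: CorpusBundle, outdir) -> None:
    """Write corpus.tsv (char + BIO label), lexicon.tsv (toy segmenter) and
    a JSON sidecar with the spec, seed and gold statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus(outdir / "corpus.tsv", bundle.sentences)
    bundle.segmenter.save(outdir / "lexicon.tsv")
    sidecar = {
        "spec": asdict(bundle.spec),
        "statistics": corpus_statistics(bundle.sentences),
    }
    (outdir / "corpus.json").write_text(
        json.dumps(sidecar, ensure_ascii=False, indent=2), encoding="utf-8"
    )
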