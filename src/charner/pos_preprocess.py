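"""Reduced part-of-speech tagging.

Clinical entities are the dominant out-of-vocabulary source for word
segmenters, so their word-level POS tags are unreliable and a long entity is
often cut into several differently-tagged pieces.  Rather than building a
medical dictionary, this preprocessing goes the other way: harvest a
*general* dictionary of non-entity word segments from the annotated training
split, keep POS tags only for segments found in that dictionary, and
collapse every other segment — i.e. the likely entities — to the reserved
tag ``"s"``, uniformly across its characters.  The result is a per-character
POS feature whose ``"s"`` blocks align with entity boundaries.

The word segmenter itself is pluggable; an external tool can be adapted by
implementing :class:`Segmenter`.  For hermetic tests the module ships a
deterministic longest-match :class:`ToySegmenter` over a fixed lexicon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

from .corpus_io import AnnotatedSentence, EntitySpan, LabelScheme, labels_to_spans

__all__ = [
    "REDUCED_TAG",
    "SegmentedSentence",
    "Segmenter",
    "ToySegmenter",
    "GeneralDictionary",
    "build_general_dictionary",
    "reduce_pos",
    "project_pos_to_chars",
    "apply_pos_tagging",
]

#: Reserved tag given to every character of an out-of-dictionary segment.
REDUCED_TAG = "s"

#: POS tag of the toy segmenter's single-character fallback.
FALLBACK_TAG = "x"


@dataclass
class SegmentedSentence:
    """A sentence cut into (word, POS) segments whose words concatenate back
    to the original text."""

    segments: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for word, pos in self.segments:
            if not word:
                raise ValueError("segments must contain non-empty words")
            if not pos:
                raise ValueError(f"segment {word!r} has an empty POS tag")

    @property
    def text(self) -> str:
        return "".join(w for w, _ in self.segments)

    def char_ranges(self) -> list[tuple[int, int]]:
        """Half-open character range of each segment."""
        ranges = []
        off = 0
        for word, _ in self.segments:
            ranges.append((off, off + len(word)))
            off += len(word)
        return ranges


@runtime_checkable
class Segmenter(Protocol):
    """Word segmenter + POS tagger contract.

    Implementations must be deterministic for fixed internal state and must
    return segments whose words concatenate exactly to the input text.
    """

    def segment(self, text: str) -> SegmentedSentence:  # pragma: no cover
        ...


class ToySegmenter:
    """Deterministic greedy longest-match segmenter over a fixed lexicon.

    Characters not covered by any lexicon word fall back to single-character
    segments tagged ``"x"``.  The reserved reduced tag ``"s"`` is rejected as
    a lexicon POS to avoid aliasing with out-of-dictionary segments.
    """

    def __init__(self, lexicon: dict[str, str]):
        for word, pos in lexicon.items():
            if not word:
                raise ValueError("lexicon words must be non-empty")
            if pos == REDUCED_TAG:
                raise ValueError(
                    f"POS tag {REDUCED_TAG!r} is reserved for reduced tagging "
                    f"(offending word: {word!r})"
                )
        self.lexicon = dict(lexicon)
        self._max_len = max((len(w) for w in lexicon), default=1)

    def segment(self, text: str) -> SegmentedSentence:
        segments: list[tuple[str, str]] = []
        i = 0
        while i < len(text):
            for j in range(min(self._max_len, len(text) - i), 0, -1):
                word = text[i:i + j]
                if word in self.lexicon:
                    segments.append((word, self.lexicon[word]))
                    i += j
                    break
            else:
                segments.append((text[i], FALLBACK_TAG))
                i += 1
        return SegmentedSentence(segments)

    def save(self, path) -> None:
        lines = [f"{w}\t{p}" for w, p in sorted(self.lexicon.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path) -> "ToySegmenter":
        lexicon = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if line.strip():
                word, pos = line.split("\t")
                lexicon[word] = pos
        return cls(lexicon)


@dataclass
class GeneralDictionary:
    """Set of non-entity word segments harvested from annotated training data."""

    words: set[str]
    n_sentences: int = 0

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)

    def save(self, path) -> None:
        Path(path).write_text(
            "\n".join(sorted(self.words)) + ("\n" if self.words else ""),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path) -> "GeneralDictionary":
        words = {w for w in Path(path).read_text(encoding="utf-8").splitlines() if w}
        return cls(words=words)


def _gold_spans(sentence: AnnotatedSentence, scheme: LabelScheme) -> list[EntitySpan]:
    if sentence.labels is None:
        raise ValueError("building the general dictionary requires gold labels")
    return labels_to_spans(sentence.labels, scheme)


def build_general_dictionary(
    corpus: Iterable[AnnotatedSentence],
    segmenter: Segmenter,
    scheme: LabelScheme | None = None,
) -> GeneralDictionary:
    """Harvest the general (non-entity) vocabulary from a training corpus.

    Every sentence is segmented; a segment enters the dictionary iff its
    character range does not intersect any gold entity span of its sentence.
    Segments partially overlapping an entity are treated as entity evidence
    and excluded.  Deterministic for a fixed corpus and segmenter.
    """
    scheme = scheme or LabelScheme()
    words: set[str] = set()
    n = 0
    for sentence in corpus:
        n += 1
        spans = _gold_spans(sentence, scheme)
        seg = segmenter.segment(sentence.text)
        for (word, _), (lo, hi) in zip(seg.segments, seg.char_ranges()):
            if not any(lo < s.end and s.start < hi for s in spans):
                words.add(word)
    if n == 0:
        warnings.warn("building a general dictionary from an empty corpus",
                      stacklevel=2)
    return GeneralDictionary(words=words, n_sentences=n)


def reduce_pos(sentence: SegmentedSentence, dictionary: GeneralDictionary) -> list[str]:
    """Reduced POS tagging of one segmented sentence.

    In-dictionary segments project their POS tag onto each of their
    characters; out-of-dictionary segments get the reserved tag ``"s"`` on
    every character.  Output length equals the sentence character count.
    """
    tags: list[str] = []
    for word, pos in sentence.segments:
        tag = pos if word in dictionary else REDUCED_TAG
        tags.extend([tag] * len(word))
    return tags


def project_pos_to_chars(sentence: SegmentedSentence) -> list[str]:
    """Plain word-to-character POS projection (the un-reduced baseline)."""
    tags: list[str] = []
    for word, pos in sentence.segments:
        tags.extend([pos] * len(word))
    return tags


def apply_pos_tagging(
    sentences: Sequence[AnnotatedSentence],
    segmenter: Segmenter,
    mode: str = "reduced",
    dictionary: GeneralDictionary | None = None,
) -> list[AnnotatedSentence]:
    """Attach a per-character POS column to each sentence.

    ``mode`` is ``"initial"`` (plain projection) or ``"reduced"`` (requires a
    ``dictionary``).  Returns new sentences; inputs are not mutated.
    """
    if mode not in ("initial", "reduced"):
        raise ValueError(f"unknown POS tagging mode {mode!r}")
    if mode == "reduced" and dictionary is None:
        raise ValueError("reduced POS tagging requires a general dictionary")
    out = []
    for sent in sentences:
        seg = segmenter.segment(sent.text)
        if mode == "initial":
            pos = project_pos_to_chars(seg)
        else:
            pos = reduce_pos(seg, dictionary)
        out.append(AnnotatedSentence(chars=list(sent.chars), pos=pos,
                                     labels=list(sent.labels) if sent.labels else None))
    return out
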