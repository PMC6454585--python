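"""Corpus I/O for character-level sequence labeling.

Corpora are plain UTF-8 column files in the CoNLL tradition: one character
per line with 1-3 whitespace-separated columns (character, optional POS tag,
optional BIO label) and a blank line between sentences.  The module also
converts between BIO label sequences and entity spans, and splits raw text
into model-sized segments at Chinese punctuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_CATEGORIES",
    "DEFAULT_DELIMITERS",
    "AnnotatedSentence",
    "EntitySpan",
    "LabelScheme",
    "CorpusParseError",
    "EmptyCorpusError",
    "LabelingError",
    "read_corpus",
    "write_corpus",
    "segment_text",
    "labels_to_spans",
    "spans_to_labels",
]

#: The five clinical entity categories of an admission record, with the
#: short codes used in label names (B_ana, I_ana, ... as in B_ope/I_ope).
DEFAULT_CATEGORIES: tuple[tuple[str, str], ...] = (
    ("AnatomicalPart", "ana"),
    ("SymptomDescription", "sym"),
    ("IndependentSymptoms", "ind"),
    ("Drug", "dru"),
    ("Operation", "ope"),
)

#: Chinese comma, period, semicolon and enumeration comma.
DEFAULT_DELIMITERS: frozenset[str] = frozenset("，。；、")


class CorpusParseError(ValueError):
    """A corpus file line that does not match the expected column layout."""


class EmptyCorpusError(ValueError):
    """A corpus file containing no sentences."""


class LabelingError(ValueError):
    """A label string outside the configured scheme, or an illegal span set."""


@dataclass
class AnnotatedSentence:
    """A sentence as a character sequence with optional per-character columns.

    ``pos`` and ``labels``, when present, are parallel to ``chars``.
    """

    chars: list[str]
    pos: list[str] | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.chars) < 1:
            raise ValueError("a sentence must contain at least one character")
        for name, seq in (("pos", self.pos), ("labels", self.labels)):
            if seq is not None and len(seq) != len(self.chars):
                raise ValueError(
                    f"{name} has length {len(seq)} but the sentence has "
                    f"{len(self.chars)} characters"
                )

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity occupying the half-open character range [start, end)."""

    category: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


class LabelScheme:
    """BIO label alphabet over an ordered set of entity categories.

    Labels are ordered ``O, B_c1, I_c1, B_c2, I_c2, ...`` so the label count
    is ``2 * n_categories + 1``.
    """

    OUTSIDE = "O"

    def __init__(self, categories: Sequence[tuple[str, str]] = DEFAULT_CATEGORIES):
        self.categories: list[str] = [name for name, _ in categories]
        self._code: dict[str, str] = dict(categories)
        codes = list(self._code.values())
        if len(set(codes)) != len(codes):
            raise ValueError("category codes must be unique")
        self._cat_of_code = {code: name for name, code in categories}
        self.labels: list[str] = [self.OUTSIDE]
        for name, code in categories:
            self.labels.append(f"B_{code}")
            self.labels.append(f"I_{code}")
        self.label_to_index: dict[str, int] = {l: i for i, l in enumerate(self.labels)}
        self.index_to_label: dict[int, str] = {i: l for i, l in enumerate(self.labels)}

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def begin(self, category: str) -> str:
        return f"B_{self._code[category]}"

    def inside(self, category: str) -> str:
        return f"I_{self._code[category]}"

    def parse(self, label: str) -> tuple[str, str | None]:
        """Split a label into (prefix, category); prefix is 'O', 'B' or 'I'."""
        if label == self.OUTSIDE:
            return "O", None
        if len(label) > 2 and label[1] == "_" and label[0] in "BI":
            code = label[2:]
            if code in self._cat_of_code:
                return label[0], self._cat_of_code[code]
        raise LabelingError(f"unknown label {label!r}")


# ---------------------------------------------------------------------------
# column-file reading / writing
# ---------------------------------------------------------------------------

def read_corpus(path, has_pos: bool = False, has_labels: bool = True) -> list[AnnotatedSentence]:
    """Read a column-format corpus file.

    Each non-blank line must carry exactly ``1 + has_pos + has_labels``
    whitespace-separated fields in the fixed order character / POS / label.
    Blank lines delimit sentences; consecutive blank lines are ignored.

    Raises
    ------
    CorpusParseError
        If a line has the wrong number of columns (the message names the
        1-based line number).
    EmptyCorpusError
        If the file contains no sentences.
    """
    expected = 1 + int(has_pos) + int(has_labels)
    sentences: list[AnnotatedSentence] = []
    chars: list[str] = []
    pos: list[str] = []
    labels: list[str] = []

    def flush() -> None:
        if chars:
            sentences.append(
                AnnotatedSentence(
                    chars=list(chars),
                    pos=list(pos) if has_pos else None,
                    labels=list(labels) if has_labels else None,
                )
            )
            chars.clear()
            pos.clear()
            labels.clear()

    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            flush()
            continue
        fields = line.split()
        if len(fields) != expected:
            raise CorpusParseError(
                f"line {lineno}: expected {expected} columns, got {len(fields)}"
            )
        chars.append(fields[0])
        if has_pos:
            pos.append(fields[1])
        if has_labels:
            labels.append(fields[-1])
    flush()
    if not sentences:
        raise EmptyCorpusError(f"no sentences found in {path}")
    return sentences


def write_corpus(path, sentences: Iterable[AnnotatedSentence]) -> None:
    """Write sentences in the column format accepted by :func:`read_corpus`."""
    lines: list[str] = []
    for sent in sentences:
        for i, ch in enumerate(sent.chars):
            fields = [ch]
            if sent.pos is not None:
                fields.append(sent.pos[i])
            if sent.labels is not None:
                fields.append(sent.labels[i])
            lines.append(" ".join(fields))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

def segment_text(text: str, delimiters: frozenset[str] | set[str] = DEFAULT_DELIMITERS) -> list[str]:
    """Split raw text into segments at Chinese punctuation marks.

    Delimiters are dropped; no empty segments are emitted, so text made
    entirely of delimiters yields an empty list.  Concatenating the segments
    with the removed delimiters reproduces the input.
    """
    if not text:
        raise ValueError("text must be non-empty")
    segments: list[str] = []
    buf: list[str] = []
    for ch in text:
        if ch in delimiters:
            if buf:
                segments.append("".join(buf))
                buf.clear()
        else:
            buf.append(ch)
    if buf:
        segments.append("".join(buf))
    return segments


# ---------------------------------------------------------------------------
# BIO labels <-> entity spans
# ---------------------------------------------------------------------------

def labels_to_spans(labels: Sequence[str], scheme: LabelScheme) -> list[EntitySpan]:
    """Decode a BIO sequence into maximal, ordered, non-overlapping spans.

    Illegal inside-tags are repaired rather than rejected (the conlleval
    convention): an ``I_c`` with no preceding ``B_c``/``I_c`` of the same
    category opens a new span of category ``c``.
    """
    spans: list[EntitySpan] = []
    cur_cat: str | None = None
    cur_start = 0
    for i, label in enumerate(labels):
        prefix, cat = scheme.parse(label)
        if prefix == "O":
            if cur_cat is not None:
                spans.append(EntitySpan(cur_cat, cur_start, i))
                cur_cat = None
        elif prefix == "B" or cat != cur_cat:
            # B always opens; I of a different category closes and re-opens
            if cur_cat is not None:
                spans.append(EntitySpan(cur_cat, cur_start, i))
            cur_cat = cat
            cur_start = i
        # else: I continuing the current span
    if cur_cat is not None:
        spans.append(EntitySpan(cur_cat, cur_start, len(labels)))
    return spans


def spans_to_labels(spans: Sequence[EntitySpan], m: int, scheme: LabelScheme) -> list[str]:
    """Encode non-overlapping spans over an ``m``-character sentence as BIO.

    Exact inverse of :func:`labels_to_spans` on legal label sequences.
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    labels = [scheme.OUTSIDE] * m
    prev_end = -1
    for span in ordered:
        if span.end > m:
            raise LabelingError(f"span {span} exceeds sentence length {m}")
        if span.start < prev_end:
            raise LabelingError(f"span {span} overlaps a previous span")
        if span.category not in scheme._code:
            raise LabelingError(f"unknown category {span.category!r}")
        labels[span.start] = scheme.begin(span.category)
        for i in range(span.start + 1, span.end):
            labels[i] = scheme.inside(span.category)
        prev_end = span.end
    return labels
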