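"""Character tokenization, punctuation-target codec, BIO span codec, sentence split.

All text is handled at the level of individual Unicode characters: clinical
records (Chinese in particular) are tagged character by character, with no
sub-word merging.  Offsets are 0-based half-open throughout.

The punctuation-correction stage is framed as tagging every *non-punctuation*
character with the punctuation mark that should follow it in the corrected
text (or NONE).  Dropping the raw text's own punctuation from the tagged
sequence lets one codec express replacement, insertion and deletion of marks
uniformly, and makes character positions invariant between the raw and the
corrected form of a document.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

NONE_TAG = "NONE"

#: Default punctuation label space: ideographic full stop, comma, enumeration
#: comma, semicolon, colon, question mark, exclamation mark.
DEFAULT_PUNCTUATION = ("。", "，", "、", "；", "：", "？", "！")

#: Sentence-final marks used by ``split_sentences``.
SENTENCE_FINAL = ("。", "？", "！")

__all__ = [
    "NONE_TAG",
    "DEFAULT_PUNCTUATION",
    "SENTENCE_FINAL",
    "CharSequence",
    "PunctuationLabelSpace",
    "Span",
    "AlignmentError",
    "BioEncodingError",
    "char_tokenize",
    "strip_punctuation",
    "punct_targets",
    "apply_punct_tags",
    "split_sentences",
    "bio_encode",
    "bio_decode",
]


class AlignmentError(ValueError):
    """Raw and corrected text differ by a non-punctuation edit, or the
    corrected text cannot be expressed in the mark-after-character frame."""


class BioEncodingError(ValueError):
    """Spans overlap or fall outside the sequence being encoded."""


@dataclass(frozen=True)
class CharSequence:
    """An ordered run of characters with per-character source offsets."""

    chars: tuple[str, ...]
    offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chars) != len(self.offsets):
            raise ValueError("chars and offsets must have equal length")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)


@dataclass(frozen=True)
class PunctuationLabelSpace:
    """The tag alphabet of the punctuation head: the marks plus NONE."""

    marks: tuple[str, ...] = DEFAULT_PUNCTUATION

    def __post_init__(self) -> None:
        if len(set(self.marks)) != len(self.marks):
            raise ValueError("punctuation marks must be unique")
        if NONE_TAG in self.marks:
            raise ValueError("NONE is reserved")

    @property
    def labels(self) -> tuple[str, ...]:
        """NONE first, then the marks — fixed index assignment."""
        return (NONE_TAG, *self.marks)

    def __contains__(self, ch: str) -> bool:
        return ch in self.marks


@dataclass(frozen=True)
class Span:
    """A labeled half-open character span of the source document."""

    label: str
    start: int
    end: int
    surface: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def char_tokenize(text: str, base_offset: int = 0) -> CharSequence:
    """One token per Unicode code point; no merging of any kind."""
    return CharSequence(
        chars=tuple(text),
        offsets=tuple(range(base_offset, base_offset + len(text))),
    )


def strip_punctuation(
    seq: CharSequence, space: PunctuationLabelSpace | None = None
) -> CharSequence:
    """Drop punctuation characters, keeping the survivors' source offsets."""
    space = space or PunctuationLabelSpace()
    kept = [(c, o) for c, o in zip(seq.chars, seq.offsets) if c not in space]
    return CharSequence(
        chars=tuple(c for c, _ in kept), offsets=tuple(o for _, o in kept)
    )


def punct_targets(
    raw: CharSequence,
    corrected: CharSequence,
    space: PunctuationLabelSpace | None = None,
) -> list[str]:
    """Tag every non-punctuation character with the mark that should follow it.

    The raw and corrected text must agree on their non-punctuation characters
    (the correction only replaces, inserts or deletes marks).  Returns one tag
    per *non-punctuation* character of the raw text.
    """
    space = space or PunctuationLabelSpace()
    raw_core = strip_punctuation(raw, space)
    corr_core = strip_punctuation(corrected, space)
    if raw_core.chars != corr_core.chars:
        raise AlignmentError(
            "raw and corrected text differ in non-punctuation characters"
        )
    tags = [NONE_TAG] * len(raw_core)
    pos = -1  # index into the non-punctuation characters seen so far
    for ch in corrected.chars:
        if ch in space:
            if pos < 0:
                raise AlignmentError("punctuation before any character")
            if tags[pos] != NONE_TAG:
                raise AlignmentError(
                    "consecutive punctuation marks cannot be encoded"
                )
            tags[pos] = ch
        else:
            pos += 1
    return tags


def apply_punct_tags(seq: CharSequence, tags: Sequence[str]) -> str:
    """Rebuild corrected text from a punctuation-free sequence and its tags."""
    if len(seq) != len(tags):
        raise ValueError(f"length mismatch: {len(seq)} chars vs {len(tags)} tags")
    out: list[str] = []
    for ch, tag in zip(seq.chars, tags):
        out.append(ch)
        if tag != NONE_TAG:
            out.append(tag)
    return "".join(out)


def split_sentences(corrected: str) -> list[CharSequence]:
    """Split corrected text on sentence-final marks, keeping the mark attached.

    Offsets index into ``corrected``.  Trailing text without a final mark is
    emitted as a last sentence; no empty sentences are produced.
    """
    sentences: list[CharSequence] = []
    start = 0
    for i, ch in enumerate(corrected):
        if ch in SENTENCE_FINAL:
            piece = corrected[start : i + 1]
            sentences.append(char_tokenize(piece, base_offset=start))
            start = i + 1
    if start < len(corrected):
        sentences.append(char_tokenize(corrected[start:], base_offset=start))
    return sentences


def _positions(seq: CharSequence) -> dict[int, int]:
    return {off: i for i, off in enumerate(seq.offsets)}


def bio_encode(spans: Iterable[Span], seq: CharSequence) -> list[str]:
    """Encode non-overlapping spans as per-character B/I/O tags over ``seq``.

    Span offsets refer to the same coordinate system as ``seq.offsets``.
    """
    tags = ["O"] * len(seq)
    pos = _positions(seq)
    claimed = [False] * len(seq)
    for sp in sorted(spans, key=lambda s: s.start):
        idx = [pos[o] for o in range(sp.start, sp.end) if o in pos]
        if not idx:
            raise BioEncodingError(f"span {sp} covers no character of the sequence")
        if any(claimed[i] for i in idx):
            raise BioEncodingError(f"span {sp} overlaps a previous span")
        for i in idx:
            claimed[i] = True
        tags[idx[0]] = f"B-{sp.label}"
        for i in idx[1:]:
            tags[i] = f"I-{sp.label}"
    return tags


def bio_decode(tags: Sequence[str], seq: CharSequence) -> list[Span]:
    """Decode B/I/O tags to spans, repairing ill-formed sequences.

    A stray ``I-x`` (after ``O``, at position 0, or after a different label)
    opens a new span — the most permissive repair, maximizing what the
    downstream attribute stage gets to see.
    """
    if len(tags) != len(seq):
        raise ValueError("tag/sequence length mismatch")
    spans: list[Span] = []
    cur_label: str | None = None
    cur_start_i = 0
    for i, tag in enumerate(tags):
        if tag == "O":
            kind, label = "O", None
        elif tag.startswith(("B-", "I-")):
            kind, label = tag[0], tag[2:]
        else:
            raise ValueError(f"malformed BIO tag {tag!r}")
        opens = kind == "B" or (kind == "I" and label != cur_label)
        if cur_label is not None and (kind == "O" or opens):
            spans.append(_close(seq, cur_label, cur_start_i, i))
            cur_label = None
        if label is not None and (opens or cur_label is None):
            cur_label, cur_start_i = label, i
    if cur_label is not None:
        spans.append(_close(seq, cur_label, cur_start_i, len(tags)))
    return spans


def _close(seq: CharSequence, label: str, i: int, j: int) -> Span:
    start = seq.offsets[i]
    end = seq.offsets[j - 1] + 1
    return Span(label=label, start=start, end=end, surface="".join(seq.chars[i:j]))
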