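"""Annotated-corpus container and its JSONL dialect.

One document per line::

    {"text": ..., "corrected_text": ...,
     "sentences":  [{"start", "end", "class"}],
     "entities":   [{"label", "start", "end"}],
     "attributes": [{"entity_index", "label", "start", "end"}]}

``text`` is the raw form (possibly with corrupted punctuation); all span
offsets index into ``corrected_text`` (0-based, half-open).  Attribute spans
point at their owning entity span by ``entity_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import schema as sm
from .seqlabels import (
    PunctuationLabelSpace,
    char_tokenize,
    punct_targets,
    strip_punctuation,
)

__all__ = ["SentenceAnn", "SpanAnn", "AnnotatedDocument", "read_jsonl", "write_jsonl"]


@dataclass(frozen=True)
class SentenceAnn:
    start: int
    end: int
    cls: str


@dataclass(frozen=True)
class SpanAnn:
    label: str
    start: int
    end: int
    entity_index: int | None = None  # set on attribute spans only


@dataclass
class AnnotatedDocument:
    """Raw text plus four aligned gold layers."""

    text: str
    corrected_text: str
    sentences: list[SentenceAnn] = field(default_factory=list)
    entities: list[SpanAnn] = field(default_factory=list)
    attributes: list[SpanAnn] = field(default_factory=list)
    doc_id: str = ""

    def validate(self, schema: sm.Schema) -> None:
        """Check layer consistency with each other and with the schema."""
        n = len(self.corrected_text)
        classes = set(sm.sentence_label_set(schema))
        for s in self.sentences:
            if not (0 <= s.start < s.end <= n):
                raise ValueError(f"sentence span [{s.start},{s.end}) out of range")
            if s.cls not in classes:
                raise ValueError(f"unknown sentence class {s.cls!r}")
        for e in self.entities:
            sm.entity_type_of(schema, e.label)  # raises on unknown entity
            if not (0 <= e.start < e.end <= n):
                raise ValueError(f"entity span [{e.start},{e.end}) out of range")
            sent = self._covering_sentence(e)
            if sent is None:
                raise ValueError(f"entity span [{e.start},{e.end}) crosses sentences")
            if e.label not in sm.entities_for_class(schema, sent.cls):
                raise ValueError(
                    f"entity {e.label!r} not allowed in class {sent.cls!r}"
                )
        for a in self.attributes:
            if a.entity_index is None or not 0 <= a.entity_index < len(self.entities):
                raise ValueError("attribute span has no valid entity_index")
            ent = self.entities[a.entity_index]
            if a.label not in sm.attributes_for(schema, ent.label):
                raise ValueError(
                    f"attribute {a.label!r} not allowed on entity {ent.label!r}"
                )
            if not (ent.start <= a.start < a.end <= ent.end):
                raise ValueError("attribute span leaves its entity segment")
        # raw and corrected must agree once punctuation is stripped
        space = PunctuationLabelSpace()
        raw_core = strip_punctuation(char_tokenize(self.text), space)
        corr_core = strip_punctuation(char_tokenize(self.corrected_text), space)
        if raw_core.chars != corr_core.chars:
            raise ValueError("raw and corrected text disagree beyond punctuation")

    def _covering_sentence(self, span: SpanAnn) -> SentenceAnn | None:
        for s in self.sentences:
            if s.start <= span.start and span.end <= s.end:
                return s
        return None

    def punct_tags(self, space: PunctuationLabelSpace | None = None) -> list[str]:
        """Gold punctuation targets derived from (text, corrected_text)."""
        return punct_targets(
            char_tokenize(self.text), char_tokenize(self.corrected_text), space
        )

    # ------------------------------------------------------------------ codec
    def to_dict(self) -> dict:
        return {
            "text": self.text,
            "corrected_text": self.corrected_text,
            "sentences": [
                {"start": s.start, "end": s.end, "class": s.cls}
                for s in self.sentences
            ],
            "entities": [
                {"label": e.label, "start": e.start, "end": e.end}
                for e in self.entities
            ],
            "attributes": [
                {
                    "entity_index": a.entity_index,
                    "label": a.label,
                    "start": a.start,
                    "end": a.end,
                }
                for a in self.attributes
            ],
            **({"doc_id": self.doc_id} if self.doc_id else {}),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotatedDocument":
        return cls(
            text=d["text"],
            corrected_text=d["corrected_text"],
            sentences=[
                SentenceAnn(s["start"], s["end"], s["class"])
                for s in d.get("sentences", [])
            ],
            entities=[
                SpanAnn(e["label"], e["start"], e["end"])
                for e in d.get("entities", [])
            ],
            attributes=[
                SpanAnn(a["label"], a["start"], a["end"], a["entity_index"])
                for a in d.get("attributes", [])
            ],
            doc_id=d.get("doc_id", ""),
        )


def read_jsonl(path: str | Path) -> list[AnnotatedDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(AnnotatedDocument.from_dict(json.loads(line)))
    return docs


def write_jsonl(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_dict(), ensure_ascii=False) + "\n")
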