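"""Inference-time composition of the four stages and object assembly.

``extract`` runs: punctuation restoration -> sentence split -> per-sentence
classification -> entity-segment tagging (label space restricted to the
sentence class) -> attribute tagging inside each segment (restricted to the
entity) -> assembly of object-level entities ready for knowledge-graph
loading.  All offsets in the result index into the *corrected* text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

from . import schema as sm
from .model import ModelBundle
from .seqlabels import (
    CharSequence,
    Span,
    apply_punct_tags,
    bio_decode,
    char_tokenize,
    split_sentences,
    strip_punctuation,
)

logger = logging.getLogger(__name__)

__all__ = ["ObjectEntity", "ExtractionResult", "extract", "assemble_objects", "to_kg_records"]


@dataclass
class ObjectEntity:
    """One extracted entity with its typed attribute spans."""

    entity_type: str
    entity: str
    segment: Span
    attributes: dict[str, list[tuple[str, int, int]]]
    sentence_index: int


@dataclass
class ExtractionResult:
    corrected_text: str
    sentences: list[tuple[CharSequence, str]]
    objects: list[ObjectEntity]
    provenance: dict = field(default_factory=dict)


def assemble_objects(
    sentence_class: str,
    entity_spans: Sequence[Span],
    attr_spans_per_entity: Sequence[Sequence[Span]],
    schema: sm.Schema,
    sentence_index: int = 0,
) -> list[ObjectEntity]:
    """Pure assembly of decoded spans into object-level entities.

    Attribute spans are clipped to their segment; attributes whose label is
    outside the entity's space are dropped with a warning (they indicate an
    upstream masking slip, not a fatal state).  An entity label outside the
    sentence class's space *is* fatal: the masking contract was violated.
    """
    allowed_entities = set(sm.entities_for_class(schema, sentence_class))
    out: list[ObjectEntity] = []
    for seg, attrs in zip(entity_spans, attr_spans_per_entity):
        if seg.label not in allowed_entities:
            raise ValueError(
                f"entity {seg.label!r} decoded in class {sentence_class!r}: "
                "label-mask violation upstream"
            )
        attr_space = set(sm.attributes_for(schema, seg.label))
        amap: dict[str, list[tuple[str, int, int]]] = {}
        for sp in attrs:
            if sp.label not in attr_space:
                logger.warning(
                    "dropping attribute %r not allowed on entity %r",
                    sp.label,
                    seg.label,
                )
                continue
            start = max(sp.start, seg.start)
            end = min(sp.end, seg.end)
            if start >= end:
                logger.warning("dropping attribute span outside its segment")
                continue
            left, right = start - sp.start, sp.end - end
            surface = sp.surface[left : len(sp.surface) - right] if sp.surface else ""
            amap.setdefault(sp.label, []).append((surface, start, end))
        out.append(
            ObjectEntity(
                entity_type=sentence_class,
                entity=seg.label,
                segment=seg,
                attributes=amap,
                sentence_index=sentence_index,
            )
        )
    return out


def extract(text: str, bundle: ModelBundle) -> ExtractionResult:
    """Run the full cascade on one document."""
    if not text:
        return ExtractionResult(corrected_text="", sentences=[], objects=[])
    raw = char_tokenize(text)
    stripped = strip_punctuation(raw, bundle.model.punct_space)
    tags = bundle.model.punct_forward(raw)
    corrected = apply_punct_tags(stripped, tags)
    sentences = split_sentences(corrected)
    result = ExtractionResult(
        corrected_text=corrected,
        sentences=[],
        objects=[],
        provenance={"punct_tags": tags, "stage_trace": []},
    )
    if len(stripped) > bundle.model.cfg.max_len:
        result.provenance["truncated"] = True
    for si, sent in enumerate(sentences):
        cls, probs = bundle.model.classify_sentence(sent)
        result.sentences.append((sent, cls))
        trace = {"sentence_index": si, "class": cls, "entities": []}
        if sm.entities_for_class(bundle.schema, cls):
            ent_tags = bundle.model.entity_forward(sent, cls)
            segments = bio_decode(ent_tags, sent)
            attr_lists: list[list[Span]] = []
            for seg in segments:
                seg_seq = char_tokenize(
                    corrected[seg.start : seg.end], base_offset=seg.start
                )
                attr_tags = bundle.model.attr_forward(seg_seq, seg.label)
                attr_lists.append(bio_decode(attr_tags, seg_seq))
                trace["entities"].append(
                    {"label": seg.label, "start": seg.start, "end": seg.end}
                )
            result.objects.extend(
                assemble_objects(cls, segments, attr_lists, bundle.schema, si)
            )
        result.provenance["stage_trace"].append(trace)
    return result


def to_kg_records(result: ExtractionResult, doc_id: str = "") -> list[str]:
    """One JSON line per object entity, with stable key order."""
    lines = []
    for obj in result.objects:
        rec = {
            "doc_id": doc_id,
            "entity_type": obj.entity_type,
            "entity": obj.entity,
            "attributes": {
                name: [{"text": t, "start": s, "end": e} for t, s, e in spans]
                for name, spans in obj.attributes.items()
            },
            "sentence_index": obj.sentence_index,
        }
        lines.append(json.dumps(rec, ensure_ascii=False))
    return lines
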