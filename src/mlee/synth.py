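"""Synthetic annotated clinical-record generator.

The original hospital corpus behind this method is access-restricted, so this
module emulates its structure: short admission-note documents, each a few
sentences long, where every sentence either describes entities of one
category (symptoms, treatments, laboratory tests, imaging) or is general
"Other" content (mental state, appetite, ...).  Each entity mention is a
contiguous segment rendered from a template whose slots are filled from typed
value lexicons (temperatures, durations, drug names, ...), giving attribute
spans learnable surface regularities.  Sentence-final periods are then
corrupted to commas at a configurable rate, mimicking the punctuation
irregularity of real records (the observed clinical rate, 48.6%, is the
default).

All four gold layers (punctuation targets, sentence classes, entity spans,
attribute spans) are emitted mutually consistent, so the generator replaces
the clinician-annotated gold standard for training and testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, model_validator

from . import schema as sm
from .corpus import AnnotatedDocument, SentenceAnn, SpanAnn
from .seqlabels import (
    PunctuationLabelSpace,
    SENTENCE_FINAL,
    char_tokenize,
    punct_targets,
    strip_punctuation,
)

__all__ = [
    "GeneratorConfig",
    "default_template_bank",
    "generate_corpus",
    "corrupt_punctuation",
    "corpus_stats",
    "CorpusStats",
]

_SLOT = re.compile(r"\{([^{}]+)\}")


# ------------------------------------------------------------- template bank

#: Typed value lexicons for attribute slots.  Values never contain
#: punctuation marks, so attribute spans survive punctuation corruption.
LEXICONS: dict[str, list[str]] = {
    "Body Temperature": ["38.5℃", "39.2℃", "37.8℃", "40.1℃", "38.9℃", "39.6℃"],
    "Occurrence": ["3天前", "2天前", "5天前", "昨日", "今晨", "1周前", "4天前"],
    "Duration": ["2天", "3天", "5小时", "1周", "半天", "4天"],
    "Aggravating Factor": ["活动后", "夜间", "受凉后", "进食后"],
    "Relieving Factor": ["休息后", "服药后", "保暖后"],
    "Cough Frequency": ["阵发性", "频繁", "偶有", "持续性"],
    "Situation": ["有痰", "无痰", "痰少", "痰多色白"],
    "Drug name": ["阿莫西林", "头孢克肟", "布洛芬", "阿奇霉素", "对乙酰氨基酚"],
    "Drug dose": ["5ml", "10mg", "0.25g", "一片", "3ml"],
    "Duration of course of treatment": ["3天", "5天", "1周", "2周"],
    "Type of operation": ["扁桃体切除术", "腺样体切除术", "支气管镜检查术"],
    "Date of operation": ["3月5日", "1月12日", "6月20日", "2月8日"],
    "Adverse reactions": ["无明显不适", "轻度恶心", "伤口少量渗血"],
    "Test item": ["白细胞计数", "C反应蛋白", "血红蛋白", "中性粒细胞比例", "降钙素原"],
    "Value": ["12.5×10^9/L", "35mg/L", "110g/L", "78%", "0.5ng/ml"],
    "Body part": ["胸部", "头部", "双肺", "颅脑"],
    "Abnormal seen": ["斑片状阴影", "未见明显异常", "少量胸腔积液", "肺纹理增粗"],
    "T1WI": ["等信号", "低信号", "稍高信号"],
    "T2WI": ["高信号", "稍高信号", "等信号"],
}

#: Per-entity segment templates; ``{Slot}`` marks an attribute sub-span.
TEMPLATES: dict[str, list[str]] = {
    "Fever": [
        "患儿{Occurrence}出现发热，体温最高{Body Temperature}，持续{Duration}",
        "{Occurrence}发热，体温{Body Temperature}",
        "发热{Duration}，最高体温{Body Temperature}",
    ],
    "Cough": [
        "{Occurrence}出现咳嗽{Duration}，{Cough Frequency}咳嗽，{Situation}，"
        "{Aggravating Factor}加重，{Relieving Factor}缓解",
        "咳嗽{Duration}，{Cough Frequency}，{Situation}",
        "{Occurrence}咳嗽，{Aggravating Factor}加重，持续{Duration}",
    ],
    "Medication Treatment": [
        "给予{Drug name}{Drug dose}口服，疗程{Duration of course of treatment}",
        "口服{Drug name}治疗，每次{Drug dose}",
        "应用{Drug name}抗感染治疗{Duration of course of treatment}",
    ],
    "Operation": [
        "于{Date of operation}行{Type of operation}，术后{Adverse reactions}",
        "行{Type of operation}，术后{Adverse reactions}",
    ],
    "Laboratory Test Entity": [
        "查{Test item}为{Value}",
        "化验示{Test item}{Value}",
    ],
    "Computed Tomography": [
        "{Body part}CT示{Abnormal seen}",
        "行{Body part}CT检查，提示{Abnormal seen}",
    ],
    "Magnetic Resonance Imaging": [
        "{Body part}核磁共振示{Abnormal seen}，T1加权像呈{T1WI}，T2加权像呈{T2WI}",
        "{Body part}磁共振检查提示{Abnormal seen}，T2加权像{T2WI}，T1加权像{T1WI}",
    ],
}

#: Distractor sentences for the reserved "Other" class (general condition).
OTHER_SENTENCES: list[str] = [
    "患儿精神状态良好，食欲正常",
    "患病以来睡眠可，大小便正常",
    "家长诉患儿精神尚可",
    "起病以来体重无明显变化",
    "患儿平素体健，无过敏史",
]


@dataclass(frozen=True)
class TemplateBank:
    templates: dict[str, list[str]]
    lexicons: dict[str, list[str]]
    other_sentences: list[str]

    def validate(self, schema: sm.Schema) -> None:
        for entity, tmpls in self.templates.items():
            space = set(sm.attributes_for(schema, entity))
            for t in tmpls:
                slots = set(_SLOT.findall(t))
                if not slots <= space:
                    raise ValueError(
                        f"template for {entity!r} uses slots {slots - space} "
                        "outside its attribute space"
                    )
                for s in slots:
                    if s not in self.lexicons:
                        raise ValueError(f"no lexicon for slot {s!r}")


def default_template_bank() -> TemplateBank:
    return TemplateBank(
        templates=TEMPLATES, lexicons=LEXICONS, other_sentences=OTHER_SENTENCES
    )


class GeneratorConfig(BaseModel):
    """Corpus-level knobs; defaults reflect the clinical conditions emulated."""

    n_documents: int = 560
    sentences_per_doc: tuple[int, int] = (2, 5)  # inclusive uniform range
    class_mixture: dict[str, float] = {
        "Symptom": 0.34,
        "Treatment": 0.18,
        "Laboratory Test": 0.16,
        "Imaging": 0.16,
        "Other": 0.16,
    }
    #: probability a Symptom sentence carries two entity segments (fever+cough)
    pair_rate: float = 0.3
    #: sentence-final period -> comma corruption probability (observed: 48.6%)
    corruption_rate: float = 0.486
    #: additional mark-deletion probability (off by default)
    deletion_rate: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture sums to {total}, expected 1")
        if not (0.0 <= self.corruption_rate <= 1.0):
            raise ValueError("corruption_rate must be in [0, 1]")
        if not (0.0 <= self.deletion_rate <= 1.0):
            raise ValueError("deletion_rate must be in [0, 1]")
        if self.sentences_per_doc[0] < 1 or self.sentences_per_doc[0] > self.sentences_per_doc[1]:
            raise ValueError("invalid sentences_per_doc range")
        return self


def _render_segment(
    entity: str, bank: TemplateBank, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, int]]]:
    """Render one entity segment; returns (text, [(attr, start, end)])."""
    tmpl = bank.templates[entity][rng.integers(len(bank.templates[entity]))]
    text_parts: list[str] = []
    attrs: list[tuple[str, int, int]] = []
    pos = 0
    cursor = 0
    for m in _SLOT.finditer(tmpl):
        literal = tmpl[cursor : m.start()]
        text_parts.append(literal)
        pos += len(literal)
        slot = m.group(1)
        value = bank.lexicons[slot][rng.integers(len(bank.lexicons[slot]))]
        text_parts.append(value)
        attrs.append((slot, pos, pos + len(value)))
        pos += len(value)
        cursor = m.end()
    tail = tmpl[cursor:]
    text_parts.append(tail)
    return "".join(text_parts), attrs


def _pick_class(mix: dict[str, float], rng: np.random.Generator) -> str:
    names = list(mix)
    return names[rng.choice(len(names), p=np.array([mix[n] for n in names]))]


def generate_corpus(
    config: GeneratorConfig,
    schema: sm.Schema | None = None,
    bank: TemplateBank | None = None,
) -> list[AnnotatedDocument]:
    """Deterministically generate a fully annotated corpus."""
    schema = schema or sm.default_schema()
    bank = bank or default_template_bank()
    bank.validate(schema)
    for cls in config.class_mixture:
        if cls == sm.OTHER_CLASS:
            continue
        missing = [
            e for e in sm.entities_for_class(schema, cls) if e not in bank.templates
        ]
        if missing:
            raise ValueError(f"template bank missing entities {missing} of {cls!r}")
    rng = np.random.default_rng(config.seed)
    docs: list[AnnotatedDocument] = []
    for di in range(config.n_documents):
        n_sent = int(
            rng.integers(config.sentences_per_doc[0], config.sentences_per_doc[1] + 1)
        )
        corrected_parts: list[str] = []
        sentences: list[SentenceAnn] = []
        entities: list[SpanAnn] = []
        attributes: list[SpanAnn] = []
        offset = 0
        for _ in range(n_sent):
            cls = _pick_class(config.class_mixture, rng)
            if cls == sm.OTHER_CLASS:
                body = bank.other_sentences[rng.integers(len(bank.other_sentences))]
                seg_list: list[tuple[str, str, list]] = []
            else:
                pool = sm.entities_for_class(schema, cls)
                if cls == "Symptom" and rng.random() < config.pair_rate:
                    chosen = [str(e) for e in rng.permutation(pool)]
                else:
                    chosen = [pool[rng.integers(len(pool))]]
                seg_list = [
                    (ent, *_render_segment(ent, bank, rng)) for ent in chosen
                ]
                body = "，".join(seg for _, seg, _ in seg_list)
            sent_start = offset
            seg_offset = sent_start
            for ent, seg_text, attrs in seg_list:
                entities.append(
                    SpanAnn(ent, seg_offset, seg_offset + len(seg_text))
                )
                ei = len(entities) - 1
                for name, a, b in attrs:
                    attributes.append(
                        SpanAnn(name, seg_offset + a, seg_offset + b, ei)
                    )
                seg_offset += len(seg_text) + 1  # +1 for the joining comma
            sentence_text = body + "。"
            corrected_parts.append(sentence_text)
            offset += len(sentence_text)
            sentences.append(SentenceAnn(sent_start, offset, cls))
        corrected = "".join(corrected_parts)
        raw = corrupt_punctuation(
            corrected, config.corruption_rate, rng, config.deletion_rate
        )
        doc = AnnotatedDocument(
            text=raw,
            corrected_text=corrected,
            sentences=sentences,
            entities=entities,
            attributes=attributes,
            doc_id=f"synthetic-{di:05d}",
        )
        doc.validate(schema)
        docs.append(doc)
    return docs


def corrupt_punctuation(
    corrected: str,
    p: float,
    rng: np.random.Generator,
    deletion_rate: float = 0.0,
) -> str:
    """Independently replace each sentence-final period with a comma w.p. ``p``;
    optionally delete any mark w.p. ``deletion_rate``."""
    space = PunctuationLabelSpace()
    out: list[str] = []
    for ch in corrected:
        if ch == "。" and rng.random() < p:
            ch = "，"
        if ch in space and deletion_rate > 0 and rng.random() < deletion_rate:
            continue
        out.append(ch)
    return "".join(out)


@dataclass
class CorpusStats:
    n_documents: int
    n_sentences: int
    n_entities: int
    n_attributes: int
    attributes_per_entity: float
    n_sentence_final_marks: int
    n_corrupted_marks: int
    corruption_rate: float
    class_counts: dict[str, int]


def corpus_stats(corpus: Sequence[AnnotatedDocument]) -> CorpusStats:
    """Exact summary counts over the gold layers of a corpus."""
    n_sent = sum(len(d.sentences) for d in corpus)
    n_ent = sum(len(d.entities) for d in corpus)
    n_attr = sum(len(d.attributes) for d in corpus)
    class_counts: dict[str, int] = {}
    for d in corpus:
        for s in d.sentences:
            class_counts[s.cls] = class_counts.get(s.cls, 0) + 1
    total_marks = 0
    corrupted = 0
    space = PunctuationLabelSpace()
    for d in corpus:
        gold = punct_targets(
            char_tokenize(d.text), char_tokenize(d.corrected_text), space
        )
        raw_seq = char_tokenize(d.text)
        raw_tags = punct_targets(raw_seq, raw_seq, space)
        for g, r in zip(gold, raw_tags):
            if g in SENTENCE_FINAL:
                total_marks += 1
                if r != g:
                    corrupted += 1
    return CorpusStats(
        n_documents=len(corpus),
        n_sentences=n_sent,
        n_entities=n_ent,
        n_attributes=n_attr,
        attributes_per_entity=(n_attr / n_ent) if n_ent else 0.0,
        n_sentence_final_marks=total_marks,
        n_corrupted_marks=corrupted,
        corruption_rate=(corrupted / total_marks) if total_marks else 0.0,
        class_counts=class_counts,
    )
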