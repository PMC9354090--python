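"""Per-stage metrics, the flattened-label baseline, and count arithmetic.

Span scoring is exact-match micro precision/recall/F1 on (label, start, end)
triples; a lenient overlap mode exists because segment boundaries can slip by
a character without hurting downstream attribute extraction.

To compare systems that see differently punctuated views of the same document
(gold corrected text, model-corrected text, raw text), spans are mapped to
*core coordinates*: the index of each character among the document's
non-punctuation characters, which is invariant under punctuation corruption
and correction.  The flattened baseline tags raw, uncorrected text with the
Cartesian ``<entity>-<attribute>`` label set and is scored on exactly the
same gold attribute tuples as the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import schema as sm
from .autodiff import Adam, Tensor
from .corpus import AnnotatedDocument
from .model import (
    BiRNN,
    CRFHead,
    Encoder,
    ModelBundle,
    ModelConfig,
    TrainConfig,
    TrainingDiverged,
    Vocab,
    _bio_table,
    _pad_batch,
)
from .pipeline import extract
from .seqlabels import (
    NONE_TAG,
    PunctuationLabelSpace,
    Span,
    bio_decode,
    bio_encode,
    char_tokenize,
    split_sentences,
    strip_punctuation,
)

__all__ = [
    "PRF",
    "MetricsReport",
    "span_prf",
    "punct_prf",
    "evaluate_stages",
    "flat_baseline",
    "printed_count_checks",
    "REFERENCE_COUNTS",
]


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float
    support: int = 0

    @staticmethod
    def from_counts(tp: int, n_pred: int, n_gold: int) -> "PRF":
        if n_pred == 0 and n_gold == 0:
            return PRF(1.0, 1.0, 1.0, 0)  # vacuous: nothing to find, nothing found
        p = tp / n_pred if n_pred else 0.0
        r = tp / n_gold if n_gold else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        return PRF(p, r, f, n_gold)


@dataclass
class MetricsReport:
    punct: PRF
    sentence_cls_precision: float
    entity: PRF
    attribute: PRF
    cascade_attribute: PRF | None = None

    def to_dict(self) -> dict:
        out = {
            "punctuation": vars(self.punct),
            "sentence_classification": {"precision": self.sentence_cls_precision},
            "entity": vars(self.entity),
            "attribute": vars(self.attribute),
        }
        if self.cascade_attribute is not None:
            out["cascade_attribute"] = vars(self.cascade_attribute)
        return out


def _match(gold: Span, pred: Span, lenient: bool) -> bool:
    if gold.label != pred.label:
        return False
    if lenient:
        return max(gold.start, pred.start) < min(gold.end, pred.end)
    return gold.start == pred.start and gold.end == pred.end


def span_prf(
    gold: Sequence[Span], pred: Sequence[Span], lenient: bool = False
) -> PRF:
    """Micro-averaged span P/R/F1; exact (label, start, end) match by default."""
    if not lenient:
        gset = {(s.label, s.start, s.end) for s in gold}
        pset = {(s.label, s.start, s.end) for s in pred}
        return PRF.from_counts(len(gset & pset), len(pset), len(gset))
    used = [False] * len(gold)
    tp = 0
    for p in pred:
        for i, g in enumerate(gold):
            if not used[i] and _match(g, p, True):
                used[i] = True
                tp += 1
                break
    return PRF.from_counts(tp, len(pred), len(gold))


def punct_prf(gold: Sequence[str], pred: Sequence[str]) -> PRF:
    """Micro P/R/F1 over non-NONE punctuation tags (NONE is the negative)."""
    if len(gold) != len(pred):
        raise ValueError("gold and predicted tag sequences must align")
    tp = sum(1 for g, p in zip(gold, pred) if g == p and g != NONE_TAG)
    n_pred = sum(1 for p in pred if p != NONE_TAG)
    n_gold = sum(1 for g in gold if g != NONE_TAG)
    return PRF.from_counts(tp, n_pred, n_gold)


# ------------------------------------------------------------ core coordinates


def _core_index(text: str, space: PunctuationLabelSpace) -> dict[int, int]:
    """Map text offset -> index among the text's non-punctuation characters."""
    out: dict[int, int] = {}
    k = 0
    for i, ch in enumerate(text):
        if ch not in space:
            out[i] = k
            k += 1
    return out


def _to_core(
    start: int, end: int, core: dict[int, int]
) -> tuple[int, int] | None:
    idx = [core[i] for i in range(start, end) if i in core]
    if not idx:
        return None
    return idx[0], idx[-1] + 1


def gold_attribute_tuples(
    doc: AnnotatedDocument, space: PunctuationLabelSpace | None = None
) -> set[tuple[str, str, int, int]]:
    """Gold (entity, attribute, core_start, core_end) tuples of one document."""
    space = space or PunctuationLabelSpace()
    core = _core_index(doc.corrected_text, space)
    out = set()
    for a in doc.attributes:
        ent = doc.entities[a.entity_index].label
        cs = _to_core(a.start, a.end, core)
        if cs is not None:
            out.add((ent, a.label, cs[0], cs[1]))
    return out


# ----------------------------------------------------------- stage evaluation


def evaluate_stages(
    bundle: ModelBundle,
    docs: Sequence[AnnotatedDocument],
    cascade: bool = True,
    lenient: bool = False,
) -> MetricsReport:
    """Score each stage on gold upstream context, plus the full cascade.

    Punctuation, entity and attribute stages report span/tag-level micro
    P/R/F1; sentence classification reports precision (micro accuracy).  With
    ``cascade=True`` the end-to-end attribute-level score (predictions flowing
    through all four stages) is also computed, in core coordinates.
    """
    space = bundle.model.punct_space
    p_tp = p_pred = p_gold = 0
    cls_ok = cls_n = 0
    ent_gold_all: list[Span] = []
    ent_pred_all: list[Span] = []
    attr_gold_all: list[Span] = []
    attr_pred_all: list[Span] = []
    cas_tp = cas_pred = cas_gold = 0
    for off, doc in enumerate(docs):
        # punctuation: corrected tags for the raw text vs gold targets
        gold_tags = doc.punct_tags(space)
        pred_tags = bundle.model.punct_forward(char_tokenize(doc.text))
        p_tp += sum(
            1 for g, p in zip(gold_tags, pred_tags) if g == p and g != NONE_TAG
        )
        p_pred += sum(1 for p in pred_tags if p != NONE_TAG)
        p_gold += sum(1 for g in gold_tags if g != NONE_TAG)
        # downstream stages on gold upstream context, offsets disambiguated
        # across documents by a large per-document stride
        stride = (off + 1) * 1_000_000
        for sent in doc.sentences:
            seq = char_tokenize(
                doc.corrected_text[sent.start : sent.end], base_offset=sent.start
            )
            pred_cls, _ = bundle.model.classify_sentence(seq)
            cls_ok += int(pred_cls == sent.cls)
            cls_n += 1
            if sm.entities_for_class(bundle.schema, sent.cls):
                tags = bundle.model.entity_forward(seq, sent.cls)
                for sp in bio_decode(tags, seq):
                    ent_pred_all.append(
                        Span(sp.label, sp.start + stride, sp.end + stride)
                    )
        for e in doc.entities:
            ent_gold_all.append(Span(e.label, e.start + stride, e.end + stride))
        for ei, ent in enumerate(doc.entities):
            seq = char_tokenize(
                doc.corrected_text[ent.start : ent.end], base_offset=ent.start
            )
            tags = bundle.model.attr_forward(seq, ent.label)
            for sp in bio_decode(tags, seq):
                attr_pred_all.append(
                    Span(f"{ent.label}-{sp.label}", sp.start + stride, sp.end + stride)
                )
            for a in doc.attributes:
                if a.entity_index == ei:
                    attr_gold_all.append(
                        Span(
                            f"{ent.label}-{a.label}",
                            a.start + stride,
                            a.end + stride,
                        )
                    )
        if cascade:
            gold_tuples = gold_attribute_tuples(doc, space)
            result = extract(doc.text, bundle)
            core = _core_index(result.corrected_text, space)
            pred_tuples = set()
            for obj in result.objects:
                for name, spans in obj.attributes.items():
                    for _, s, e in spans:
                        cs = _to_core(s, e, core)
                        if cs is not None:
                            pred_tuples.add((obj.entity, name, cs[0], cs[1]))
            cas_tp += len(gold_tuples & pred_tuples)
            cas_pred += len(pred_tuples)
            cas_gold += len(gold_tuples)
    return MetricsReport(
        punct=PRF.from_counts(p_tp, p_pred, p_gold),
        sentence_cls_precision=cls_ok / cls_n if cls_n else 1.0,
        entity=span_prf(ent_gold_all, ent_pred_all, lenient),
        attribute=span_prf(attr_gold_all, attr_pred_all, lenient),
        cascade_attribute=(
            PRF.from_counts(cas_tp, cas_pred, cas_gold) if cascade else None
        ),
    )


# ------------------------------------------------------------- flat baseline


class FlatTagger:
    """Single-stage baseline: one BIO tagger over the flattened label set.

    Tags raw (uncorrected, comma-ridden) text units with
    ``<entity>-<attribute>`` labels directly — no punctuation correction, no
    sentence classification, no label-space restriction.  Shares the cascade's
    encoder architecture so the comparison isolates the method, not capacity.
    """

    def __init__(self, schema: sm.Schema, vocab: Vocab, cfg: ModelConfig):
        flat = sm.flatten(schema)
        if not flat:
            raise ValueError("schema has zero flat labels")
        if cfg.vocab_size == 0:
            cfg = cfg.model_copy(update={"vocab_size": len(vocab)})
        self.schema, self.vocab, self.cfg = schema, vocab, cfg
        self.labels = _bio_table([f.text for f in flat])
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg, rng)
        self.rnn = BiRNN(cfg.embed_dim, cfg.rnn_dim, rng, "flat_rnn")
        self.head = CRFHead(
            2 * cfg.rnn_dim, self.labels, rng, "flat", cfg.crf == "on", bio=True
        )

    def named_params(self) -> dict[str, Tensor]:
        return {**self.encoder.params, **self.rnn.params, **self.head.params}

    def _units(self, doc: AnnotatedDocument) -> list:
        return [u for u in split_sentences(doc.text) if len(u)]

    def _gold_tags(self, doc: AnnotatedDocument, unit) -> list[str]:
        space = PunctuationLabelSpace()
        core_corr = _core_index(doc.corrected_text, space)
        core_raw = _core_index(doc.text, space)
        raw_of_core = {v: k for k, v in core_raw.items()}
        spans = []
        for a in doc.attributes:
            ent = doc.entities[a.entity_index].label
            cs = _to_core(a.start, a.end, core_corr)
            if cs is None:
                continue
            # attribute values contain no punctuation, so they stay contiguous
            rs, re = raw_of_core[cs[0]], raw_of_core[cs[1] - 1] + 1
            if unit.offsets[0] <= rs and re <= unit.offsets[-1] + 1:
                spans.append(Span(f"{ent}-{a.label}", rs, re))
        return bio_encode(spans, unit)

    def train(self, corpus: Sequence[AnnotatedDocument], tc: TrainConfig) -> None:
        items: list[tuple[np.ndarray, np.ndarray]] = []
        index = {lab: i for i, lab in enumerate(self.labels)}
        for doc in corpus:
            for unit in self._units(doc):
                ids = self.vocab.encode(unit.chars)[: self.cfg.max_len]
                tags = self._gold_tags(doc, unit)[: len(ids)]
                items.append((ids, np.array([index[t] for t in tags], dtype=int)))
        opt = Adam(list(self.named_params().values()), lr=tc.lr)
        rng = np.random.default_rng(tc.seed + 2)
        drop_rng = np.random.default_rng(tc.seed + 4)
        order = np.arange(len(items))
        # batch in sentence units, matching the cascade's per-document batches
        bsz = tc.batch_size * 3
        for epoch in range(tc.epochs):
            opt.lr = tc.lr_at(epoch)  # same schedule as the cascade, for fairness
            rng.shuffle(order)
            for lo in range(0, len(items), bsz):
                chunk = [items[i] for i in order[lo : lo + bsz]]
                ids, gold, lengths = _pad_batch(
                    [c[0] for c in chunk], [c[1] for c in chunk]
                )
                ctx, _ = self.encoder(ids, lengths, drop_rng=drop_rng)
                em = self.head.emissions(self.rnn(ctx))
                mask = np.ones((len(chunk), len(self.labels)), dtype=bool)
                loss = self.head.nll(em, lengths, gold, mask)
                if not np.isfinite(loss.data):
                    raise TrainingDiverged(f"flat baseline diverged at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()

    def predict_tuples(
        self, doc: AnnotatedDocument
    ) -> set[tuple[str, str, int, int]]:
        space = PunctuationLabelSpace()
        core_raw = _core_index(doc.text, space)
        out = set()
        for unit in self._units(doc):
            ids = self.vocab.encode(unit.chars)[: self.cfg.max_len][None, :]
            ctx, _ = self.encoder(ids, np.array([ids.shape[1]]))
            em = self.head.emissions(self.rnn(ctx)).data[0]
            tags = self.head.decode(em, set(self.labels))
            for sp in bio_decode(tags, unit):
                try:
                    flat = sm.FlatLabel.parse(sp.label, self.schema)
                except sm.SchemaError:
                    continue
                cs = _to_core(sp.start, sp.end, core_raw)
                if cs is not None:
                    out.add((flat.entity, flat.attribute, cs[0], cs[1]))
        return out


@dataclass
class BaselineComparison:
    cascade_attribute_f1: float
    baseline_attribute_f1: float
    delta: float  # cascade minus baseline; positive favors the cascade
    baseline: PRF
    cascade: PRF


def flat_baseline(
    train_docs: Sequence[AnnotatedDocument],
    test_docs: Sequence[AnnotatedDocument],
    bundle: ModelBundle,
    train_config: TrainConfig | None = None,
    cascade_prf: PRF | None = None,
) -> BaselineComparison:
    """Train the flattened single-stage tagger and compare attribute-level F1.

    Both systems are scored against identical gold (entity, attribute,
    core-span) tuples on the same test documents.  A precomputed cascade
    score may be passed to avoid re-running the extraction pipeline.
    """
    tc = train_config or bundle.train_config
    tagger = FlatTagger(bundle.schema, bundle.model.vocab, bundle.model.cfg)
    tagger.train(train_docs, tc)
    tp_b = pred_b = n_gold = 0
    for doc in test_docs:
        gold = gold_attribute_tuples(doc)
        n_gold += len(gold)
        pb = tagger.predict_tuples(doc)
        tp_b += len(gold & pb)
        pred_b += len(pb)
    baseline = PRF.from_counts(tp_b, pred_b, n_gold)
    cascade = cascade_prf
    if cascade is None:
        cascade_report = evaluate_stages(bundle, test_docs, cascade=True)
        cascade = cascade_report.cascade_attribute
    assert cascade is not None
    return BaselineComparison(
        cascade_attribute_f1=cascade.f1,
        baseline_attribute_f1=baseline.f1,
        delta=cascade.f1 - baseline.f1,
        baseline=baseline,
        cascade=cascade,
    )


# ------------------------------------------------------- printed-count checks

#: Published summary counts of the original (access-restricted) clinical
#: corpus: sentences annotated, punctuation points manually corrected,
#: entities, attributes, and the two derived figures as printed.
REFERENCE_COUNTS = {
    "sentences": 7029,
    "corrected_punctuation_points": 3418,
    "entities": 10467,
    "attributes": 29478,
    "printed_attributes_per_entity": 2.82,
    "printed_punctuation_error_rate_pct": 48.6,
}


def printed_count_checks(counts: dict | None = None) -> dict:
    """Recompute the derived corpus figures from the raw printed counts."""
    c = counts or REFERENCE_COUNTS
    attrs_per_entity = (
        round(c["attributes"] / c["entities"], 2) if c["entities"] else 0.0
    )
    err_rate = (
        round(100.0 * c["corrected_punctuation_points"] / c["sentences"], 1)
        if c["sentences"]
        else 0.0
    )
    report = {
        "attributes_per_entity": attrs_per_entity,
        "punctuation_error_rate_pct": err_rate,
    }
    if "printed_attributes_per_entity" in c:
        report["attributes_per_entity_matches"] = (
            attrs_per_entity == c["printed_attributes_per_entity"]
        )
    if "printed_punctuation_error_rate_pct" in c:
        report["punctuation_error_rate_matches"] = (
            err_rate == c["printed_punctuation_error_rate_pct"]
        )
    return report
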