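"""Shared encoder, the four task heads, the summed joint loss, and training.

The architecture mirrors the cascade it serves: one character-level encoder
(a small transformer: embeddings + self-attention blocks) feeds

* a punctuation head (linear + CRF) over punctuation-stripped document text,
* a sentence classifier (linear + softmax) on the summary vector,
* an entity-segment head (bidirectional recurrent layer + linear + CRF) whose
  label space is restricted to the sentence class's entities, and
* an attribute head (same shape) restricted to the segment entity's attributes.

All four losses are negative log-likelihoods summed over their tokens or
sentences, and the joint loss is their plain (unweighted) sum:

    L_total = L_punct + L_entity + L_attr + L_cls

Training is joint: every minibatch of documents contributes all four terms
through the shared encoder.  Downstream heads train on gold upstream context
(teacher forcing); at inference the cascade feeds them predictions.

The encoder is deliberately small and trainable from scratch; anything
exposing the same interface (per-character context vectors plus a summary
vector) can be swapped in, including a pretrained one.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel

from . import schema as sm
from .autodiff import Adam, Tensor, concat, crf_forward_step, dropout, stack
from .corpus import AnnotatedDocument
from .crf import TransitionScores, viterbi
from .seqlabels import (
    CharSequence,
    NONE_TAG,
    PunctuationLabelSpace,
    Span,
    bio_encode,
    char_tokenize,
    punct_targets,
    strip_punctuation,
)

NEG = -1e30

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Vocab",
    "LossBreakdown",
    "MultiTaskModel",
    "ModelBundle",
    "TrainingDiverged",
    "train",
]


class TrainingDiverged(RuntimeError):
    pass


class ModelConfig(BaseModel):
    """Encoder and head hyperparameters.

    ``crf`` switches the tagging heads between sequence-level CRF likelihood
    (``"on"``) and per-token cross-entropy (``"off"``, transitions frozen at
    zero).  ``reduction`` chooses sum (the default, matching the summed joint
    loss) or mean reduction of each component.
    """

    vocab_size: int = 0  # filled in when the vocabulary is built
    embed_dim: int = 64
    n_layers: int = 2
    n_heads: int = 2
    ffn_dim: int = 96
    rnn_dim: int = 32
    dropout: float = 0.1
    max_len: int = 256
    #: side-feature vocabulary (punctuation-mark-after-character, incl. NONE)
    n_feat: int = 8
    crf: str = "on"
    reduction: str = "sum"
    seed: int = 0


class TrainConfig(BaseModel):
    epochs: int = 30
    batch_size: int = 16
    lr: float = 2e-3
    #: cosine decay of the learning rate down to lr_min_factor * lr
    lr_min_factor: float = 0.1
    #: "joint" trains all four tasks every batch; "staged" trains them one
    #: after another (punct, cls, entity, attr), for ablation
    schedule: str = "joint"
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        """Cosine-annealed learning rate for a given epoch (0-based)."""
        if self.epochs <= 1:
            return self.lr
        frac = 0.5 * (1.0 + np.cos(np.pi * epoch / (self.epochs - 1)))
        return self.lr * (self.lr_min_factor + (1.0 - self.lr_min_factor) * frac)


class Vocab:
    """Character vocabulary; id 0 is padding, id 1 is unknown."""

    PAD, UNK = 0, 1

    def __init__(self, chars: Sequence[str]):
        self.chars = list(chars)
        self.index = {c: i + 2 for i, c in enumerate(self.chars)}

    @classmethod
    def from_texts(cls, texts: Sequence[str]) -> "Vocab":
        seen: list[str] = []
        known: set[str] = set()
        for t in texts:
            for ch in t:
                if ch not in known:
                    known.add(ch)
                    seen.append(ch)
        return cls(sorted(seen))  # sorted: independent of corpus order

    def __len__(self) -> int:
        return len(self.chars) + 2

    def encode(self, chars: Sequence[str]) -> np.ndarray:
        return np.array([self.index.get(c, self.UNK) for c in chars], dtype=int)


@dataclass
class LossBreakdown:
    """The four component losses, their sums, and per-task token counts."""

    loss_punct: float = 0.0
    loss_entity: float = 0.0
    loss_attr: float = 0.0
    loss_cls: float = 0.0
    m_punct_tokens: int = 0
    n_entity_tokens: int = 0
    n_attr_tokens: int = 0
    h_sentences: int = 0

    @property
    def loss_seq_total(self) -> float:
        return self.loss_punct + self.loss_entity + self.loss_attr

    @property
    def loss_total(self) -> float:
        return self.loss_seq_total + self.loss_cls

    def __add__(self, other: "LossBreakdown") -> "LossBreakdown":
        return LossBreakdown(
            self.loss_punct + other.loss_punct,
            self.loss_entity + other.loss_entity,
            self.loss_attr + other.loss_attr,
            self.loss_cls + other.loss_cls,
            self.m_punct_tokens + other.m_punct_tokens,
            self.n_entity_tokens + other.n_entity_tokens,
            self.n_attr_tokens + other.n_attr_tokens,
            self.h_sentences + other.h_sentences,
        )


# --------------------------------------------------------------------- layers


def _init(rng: np.random.Generator, *shape: int, scale: float = 0.08) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def _linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x (..., d) @ w (d, k) as one flat GEMM (faster than stacked matmul)."""
    lead = x.shape[:-1]
    y = x.reshape(-1, x.shape[-1]) @ w
    y = y.reshape(*lead, w.shape[-1])
    return y + b if b is not None else y


def _zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Encoder:
    """Character embeddings + relative-position self-attention blocks.

    Position is encoded as a clipped relative-distance bias added to the
    attention scores (per head, per layer) rather than absolute position
    embeddings: punctuation and tagging decisions depend on local context,
    and a translation-invariant encoding generalizes across positions in
    documents of any length.

    A learned summary slot is prepended at position 0; its output is the
    sentence summary vector, outputs 1..T are the per-character context.
    """

    REL_CLIP = 8  # relative distances beyond ±8 share one bias bucket

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d = cfg.embed_dim
        self.cfg = cfg
        self.params: dict[str, Tensor] = {
            "emb": _init(rng, cfg.vocab_size, d),
            "feat_emb": _init(rng, cfg.n_feat, d),  # per-char side features
            "cls_vec": _init(rng, d),
        }
        for i in range(cfg.n_layers):
            p = self.params
            p[f"l{i}.wq"] = _init(rng, d, d)
            p[f"l{i}.wk"] = _init(rng, d, d)
            p[f"l{i}.wv"] = _init(rng, d, d)
            p[f"l{i}.wo"] = _init(rng, d, d)
            p[f"l{i}.rel"] = _zeros(cfg.n_heads, 2 * self.REL_CLIP + 1)
            p[f"l{i}.w1"] = _init(rng, d, cfg.ffn_dim)
            p[f"l{i}.b1"] = _zeros(cfg.ffn_dim)
            p[f"l{i}.w2"] = _init(rng, cfg.ffn_dim, d)
            p[f"l{i}.b2"] = _zeros(d)

    def __call__(
        self,
        ids: np.ndarray,
        lengths: np.ndarray,
        feat_ids: np.ndarray | None = None,
        drop_rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """ids (B, T) int, lengths (B,) -> context (B, T, d), summary (B, d).

        ``feat_ids`` optionally adds a per-character side-feature embedding
        (the punctuation task passes the raw text's own following-mark here:
        the stage corrects existing marks rather than restoring from nothing).
        ``drop_rng`` enables dropout (training only; None at inference).
        """
        cfg, p = self.cfg, self.params
        B, T = ids.shape
        d, H = cfg.embed_dim, cfg.n_heads
        dh = d // H
        x = p["emb"][ids] if T else None
        if x is not None and feat_ids is not None:
            x = x + p["feat_emb"][feat_ids]
        cls_tok = p["cls_vec"].reshape(1, 1, d) * np.ones((B, 1, 1))
        x = concat([cls_tok, x], axis=1) if x is not None else cls_tok
        x = dropout(x, cfg.dropout, drop_rng)
        # key positions beyond each sequence's length are never attended to
        key_pad = np.arange(T + 1)[None, :] > lengths[:, None]  # (B, T+1)
        pos = np.arange(T + 1)
        rel = np.clip(pos[None, :] - pos[:, None], -self.REL_CLIP, self.REL_CLIP)
        rel_idx = rel + self.REL_CLIP  # (T+1, T+1) bucket indices
        for i in range(cfg.n_layers):
            h = x.layernorm()
            q = _linear(h, p[f"l{i}.wq"]).reshape(B, T + 1, H, dh).swapaxes(1, 2)
            k = _linear(h, p[f"l{i}.wk"]).reshape(B, T + 1, H, dh).swapaxes(1, 2)
            v = _linear(h, p[f"l{i}.wv"]).reshape(B, T + 1, H, dh).swapaxes(1, 2)
            scores = (q @ k.swapaxes(2, 3)) * (1.0 / np.sqrt(dh))
            scores = scores + p[f"l{i}.rel"][:, rel_idx]  # (H, T+1, T+1) bias
            scores = scores.masked_fill(key_pad[:, None, None, :], -1e9)
            att = scores.softmax(axis=-1) @ v  # (B, H, T+1, dh)
            att = _linear(att.swapaxes(1, 2).reshape(B, T + 1, d), p[f"l{i}.wo"])
            x = x + dropout(att, cfg.dropout, drop_rng)
            h = x.layernorm()
            ffn = _linear(
                _linear(h, p[f"l{i}.w1"], p[f"l{i}.b1"]).relu(),
                p[f"l{i}.w2"],
                p[f"l{i}.b2"],
            )
            x = x + dropout(ffn, cfg.dropout, drop_rng)
        x = x.layernorm()
        summary = x[:, 0, :]
        context = x[:, 1:, :] if T else Tensor(np.zeros((B, 0, d)))
        # zero out padded positions so the recurrent heads see clean input
        valid = (np.arange(T)[None, :] < lengths[:, None])[:, :, None]
        context = context * valid
        return context, summary


class BiRNN:
    """Single-layer bidirectional tanh recurrence over context vectors."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, prefix: str):
        self.hidden = hidden
        self.prefix = prefix
        self.params = {
            f"{prefix}.wx_f": _init(rng, in_dim, hidden),
            f"{prefix}.wh_f": _init(rng, hidden, hidden),
            f"{prefix}.b_f": _zeros(hidden),
            f"{prefix}.wx_b": _init(rng, in_dim, hidden),
            f"{prefix}.wh_b": _init(rng, hidden, hidden),
            f"{prefix}.b_b": _zeros(hidden),
        }

    def __call__(self, x: Tensor) -> Tensor:
        """(B, T, d) -> (B, T, 2*hidden)."""
        p, pre = self.params, self.prefix
        B, T, _ = x.shape
        if T == 0:
            return Tensor(np.zeros((B, 0, 2 * self.hidden)))
        # hoist the input projections out of the recurrence: one GEMM each
        xf = _linear(x, p[f"{pre}.wx_f"], p[f"{pre}.b_f"])
        xb = _linear(x, p[f"{pre}.wx_b"], p[f"{pre}.b_b"])
        fwd: list[Tensor] = []
        h = Tensor(np.zeros((B, self.hidden)))
        for t in range(T):
            h = (xf[:, t, :] + h @ p[f"{pre}.wh_f"]).tanh()
            fwd.append(h)
        bwd: list[Tensor] = [None] * T  # type: ignore[list-item]
        h = Tensor(np.zeros((B, self.hidden)))
        for t in range(T - 1, -1, -1):
            h = (xb[:, t, :] + h @ p[f"{pre}.wh_b"]).tanh()
            bwd[t] = h
        return concat(
            [stack(fwd, axis=1), stack(bwd, axis=1)], axis=-1
        )


class CRFHead:
    """Linear projection to emissions plus a linear-chain CRF layer.

    BIO well-formedness (when the label table is a BIO alphabet) is enforced
    through constant ``-inf`` entries added to the transition and start
    scores.  With ``crf="off"`` the learned transition parameters are frozen
    at zero, which reduces the loss to per-token cross-entropy.
    """

    def __init__(
        self,
        in_dim: int,
        labels: Sequence[str],
        rng: np.random.Generator,
        prefix: str,
        crf_on: bool,
        bio: bool,
    ):
        L = len(labels)
        self.labels = list(labels)
        self.prefix = prefix
        self.crf_on = crf_on
        self.params = {
            f"{prefix}.w": _init(rng, in_dim, L),
            f"{prefix}.b": _zeros(L),
        }
        if crf_on:
            self.params[f"{prefix}.trans"] = _zeros(L, L)
            self.params[f"{prefix}.start"] = _zeros(L)
            self.params[f"{prefix}.end"] = _zeros(L)
        self.trans_con = np.zeros((L, L))
        self.start_con = np.zeros(L)
        if bio:
            for j, lab in enumerate(self.labels):
                if lab.startswith("I-"):
                    self.start_con[j] = NEG
                    for i, prev in enumerate(self.labels):
                        if prev not in (f"B-{lab[2:]}", lab):
                            self.trans_con[i, j] = NEG

    # ----------------------------------------------------------- training side
    def emissions(self, x: Tensor) -> Tensor:
        return _linear(
            x, self.params[f"{self.prefix}.w"], self.params[f"{self.prefix}.b"]
        )

    def _trans(self) -> tuple[Tensor, Tensor, Tensor]:
        # crf="off": all transition scores are exactly zero (no learned
        # potentials, no structural constraints) -> per-token cross-entropy.
        L = len(self.labels)
        if self.crf_on:
            p = self.params
            return (
                p[f"{self.prefix}.trans"] + self.trans_con,
                p[f"{self.prefix}.start"] + self.start_con,
                p[f"{self.prefix}.end"],
            )
        zero = np.zeros(L)
        return (Tensor(np.zeros((L, L))), Tensor(zero), Tensor(zero.copy()))

    def nll(
        self,
        em: Tensor,
        lengths: np.ndarray,
        gold: np.ndarray,
        label_mask: np.ndarray,
    ) -> Tensor:
        """Summed sequence NLL over a padded batch.

        em (B, T, L); gold (B, T) int (padding arbitrary); label_mask (B, L)
        bool — True where a label is decodable for that sequence.
        """
        B, T, L = em.shape
        trans, start, end = self._trans()
        em = em.masked_fill(~label_mask[:, None, :], NEG)
        # gold path score
        b_idx, t_idx = np.nonzero(np.arange(T)[None, :] < lengths[:, None])
        score = em[b_idx, t_idx, gold[b_idx, t_idx]].sum()
        prev_mask = np.arange(1, T)[None, :] < lengths[:, None]
        pb, pt = np.nonzero(prev_mask)
        if len(pb):
            score = score + trans[gold[pb, pt], gold[pb, pt + 1]].sum()
        last = lengths - 1
        score = score + start[gold[:, 0]].sum() + end[gold[np.arange(B), last]].sum()
        # partition function
        alpha = start.reshape(1, L) + em[:, 0, :]
        for t in range(1, T):
            nxt = crf_forward_step(alpha, trans) + em[:, t, :]
            active = (t < lengths)[:, None]
            alpha = nxt.where_static(active, alpha)
        logz = (alpha + end.reshape(1, L)).logsumexp(axis=1).sum()
        return logz - score

    # ---------------------------------------------------------- inference side
    def decode(self, em: np.ndarray, allowed: Sequence[str]) -> list[str]:
        """Viterbi-decode numpy emissions under a label-subset mask."""
        if em.shape[0] == 0:
            return []
        if self.crf_on:
            p = self.params
            tr = TransitionScores(
                matrix=p[f"{self.prefix}.trans"].data + self.trans_con,
                start=p[f"{self.prefix}.start"].data + self.start_con,
                end=p[f"{self.prefix}.end"].data.copy(),
            )
        else:
            tr = TransitionScores.zeros(len(self.labels))
        mask = np.array([lab in allowed for lab in self.labels])
        path = viterbi(em, tr, mask)
        return [self.labels[i] for i in path]


def _bio_table(names: Sequence[str]) -> list[str]:
    out = ["O"]
    for n in names:
        out += [f"B-{n}", f"I-{n}"]
    return out


def _pad_batch(
    seqs: list[np.ndarray], golds: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    B = len(seqs)
    T = max(len(s) for s in seqs)
    ids = np.zeros((B, T), dtype=int)
    gold = np.zeros((B, T), dtype=int)
    lengths = np.array([len(s) for s in seqs])
    for i, (s, g) in enumerate(zip(seqs, golds)):
        ids[i, : len(s)] = s
        gold[i, : len(g)] = g
    return ids, gold, lengths


def _length_chunks(
    lengths: list[int], token_budget: int = 4096, max_seqs: int = 96
) -> list[list[int]]:
    """Group item indices by similar length to limit padding waste.

    Sorting by length and chunking under a padded-token budget keeps the
    quadratic attention cost of long outliers away from short sequences.
    """
    order = sorted(range(len(lengths)), key=lambda i: lengths[i])
    chunks: list[list[int]] = []
    cur: list[int] = []
    for i in order:
        tmax = lengths[i]  # ascending, so the newest item is the longest
        if cur and ((len(cur) + 1) * tmax > token_budget or len(cur) >= max_seqs):
            chunks.append(cur)
            cur = []
        cur.append(i)
    if cur:
        chunks.append(cur)
    return chunks


# ---------------------------------------------------------------------- model


class MultiTaskModel:
    def __init__(self, schema: sm.Schema, vocab: Vocab, cfg: ModelConfig):
        if cfg.vocab_size == 0:
            cfg = cfg.model_copy(update={"vocab_size": len(vocab)})
        self.schema = schema
        self.vocab = vocab
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)

        self.punct_space = PunctuationLabelSpace()
        if cfg.n_feat < len(self.punct_space.labels):
            cfg = cfg.model_copy(update={"n_feat": len(self.punct_space.labels)})
            self.cfg = cfg
        self.class_labels = sm.sentence_label_set(schema)
        self.entity_labels = _bio_table(schema.entity_names())
        self.attr_labels = _bio_table(schema.attribute_names())

        d, r = cfg.embed_dim, cfg.rnn_dim
        crf_on = cfg.crf == "on"
        #: set by the training loop; None means inference (no dropout)
        self._drop_rng: np.random.Generator | None = None
        self.encoder = Encoder(cfg, rng)
        self.punct_head = CRFHead(
            d, self.punct_space.labels, rng, "punct", crf_on, bio=False
        )
        self.cls_params = {
            "cls.w": _init(rng, d, len(self.class_labels)),
            "cls.b": _zeros(len(self.class_labels)),
        }
        self.entity_rnn = BiRNN(d, r, rng, "ent_rnn")
        self.entity_head = CRFHead(2 * r, self.entity_labels, rng, "ent", crf_on, True)
        self.attr_rnn = BiRNN(d, r, rng, "attr_rnn")
        self.attr_head = CRFHead(2 * r, self.attr_labels, rng, "attr", crf_on, True)

    # ------------------------------------------------------------------ params
    def named_params(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        out.update(self.encoder.params)
        out.update(self.punct_head.params)
        out.update(self.cls_params)
        out.update(self.entity_rnn.params)
        out.update(self.entity_head.params)
        out.update(self.attr_rnn.params)
        out.update(self.attr_head.params)
        return out

    # --------------------------------------------------------- label-space maps
    def _entity_mask(self, cls: str) -> np.ndarray:
        allowed = {"O"}
        for e in sm.entities_for_class(self.schema, cls):
            allowed |= {f"B-{e}", f"I-{e}"}
        return np.array([lab in allowed for lab in self.entity_labels])

    def _attr_mask(self, entity: str) -> np.ndarray:
        allowed = {"O"}
        for a in sm.attributes_for(self.schema, entity):
            allowed |= {f"B-{a}", f"I-{a}"}
        return np.array([lab in allowed for lab in self.attr_labels])

    def _ids(self, chars: Sequence[str]) -> np.ndarray:
        ids = self.vocab.encode(chars)
        if len(ids) > self.cfg.max_len:
            warnings.warn(
                f"sequence of length {len(ids)} truncated to max_len={self.cfg.max_len}"
            )
            ids = ids[: self.cfg.max_len]
        return ids

    # -------------------------------------------------------------- joint loss
    TASKS = ("punct", "cls", "entity", "attr")

    def joint_loss(
        self,
        docs: Sequence[AnnotatedDocument],
        tasks: Sequence[str] | None = None,
    ) -> tuple[Tensor, LossBreakdown]:
        """Summed four-task loss over a batch of fully annotated documents.

        ``tasks`` restricts which heads contribute (staged training /
        ablation); excluded tasks contribute exactly zero.
        """
        active = set(self.TASKS if tasks is None else tasks)
        if not active <= set(self.TASKS):
            raise ValueError(f"unknown tasks {active - set(self.TASKS)}")
        bd = LossBreakdown()

        # --- punctuation task: stripped raw text, mark-after-character tags;
        # the raw text's own marks enter as per-character side features (the
        # stage corrects existing punctuation, it does not restore blind)
        p_ids, p_gold, p_feat = [], [], []
        punct_index = {lab: i for i, lab in enumerate(self.punct_space.labels)}
        for doc in docs if "punct" in active else []:
            raw = char_tokenize(doc.text)
            stripped = strip_punctuation(raw, self.punct_space)
            if len(stripped) == 0:
                continue
            tags = doc.punct_tags(self.punct_space)
            raw_tags = punct_targets(raw, raw, self.punct_space)
            n = min(len(stripped), self.cfg.max_len)
            p_ids.append(self._ids(stripped.chars))
            p_gold.append(np.array([punct_index[t] for t in tags[:n]], dtype=int))
            p_feat.append(
                np.array([punct_index[t] for t in raw_tags[:n]], dtype=int)
            )
        loss_punct = Tensor(0.0)
        for chunk in _length_chunks([len(s) for s in p_ids]) if p_ids else []:
            ids, gold, lengths = _pad_batch(
                [p_ids[i] for i in chunk], [p_gold[i] for i in chunk]
            )
            feats, _, _ = _pad_batch(
                [p_feat[i] for i in chunk], [p_feat[i] for i in chunk]
            )
            ctx, _ = self.encoder(
                ids, lengths, feat_ids=feats, drop_rng=self._drop_rng
            )
            em = self.punct_head.emissions(ctx)
            mask = np.ones((len(chunk), len(self.punct_space.labels)), dtype=bool)
            loss_punct = loss_punct + self.punct_head.nll(em, lengths, gold, mask)
            bd.m_punct_tokens += int(lengths.sum())

        # --- sentence batch: classification plus entity tagging (shared encode)
        s_ids, s_gold_cls, s_ent_gold, s_ent_mask, s_is_ent = [], [], [], [], []
        ent_index = {lab: i for i, lab in enumerate(self.entity_labels)}
        cls_index = {c: i for i, c in enumerate(self.class_labels)}
        for doc in docs if active & {"cls", "entity"} else []:
            for sent in doc.sentences:
                seq = char_tokenize(
                    doc.corrected_text[sent.start : sent.end], base_offset=sent.start
                )
                if len(seq) == 0:
                    continue
                ids = self._ids(seq.chars)
                s_ids.append(ids)
                s_gold_cls.append(cls_index[sent.cls])
                spans = [
                    Span(e.label, e.start, e.end)
                    for e in doc.entities
                    if sent.start <= e.start and e.end <= sent.end
                ]
                tags = bio_encode(spans, seq)[: len(ids)]
                s_ent_gold.append(np.array([ent_index[t] for t in tags], dtype=int))
                s_ent_mask.append(self._entity_mask(sent.cls))
                s_is_ent.append(sent.cls != sm.OTHER_CLASS)
        loss_cls = Tensor(0.0)
        loss_entity = Tensor(0.0)
        for chunk in _length_chunks([len(s) for s in s_ids]) if s_ids else []:
            ids, gold_tags, lengths = _pad_batch(
                [s_ids[i] for i in chunk], [s_ent_gold[i] for i in chunk]
            )
            ctx, summary = self.encoder(ids, lengths, drop_rng=self._drop_rng)
            if "cls" in active:
                logits = (
                    summary @ self.cls_params["cls.w"] + self.cls_params["cls.b"]
                )
                gold_cls = np.array([s_gold_cls[i] for i in chunk])
                loss_cls = loss_cls + (
                    logits.logsumexp(axis=-1)
                    - logits[np.arange(len(chunk)), gold_cls]
                ).sum()
                bd.h_sentences += len(chunk)
            rows = (
                np.nonzero([s_is_ent[i] for i in chunk])[0]
                if "entity" in active
                else np.array([], dtype=int)
            )
            if len(rows):
                h = self.entity_rnn(ctx[rows])
                em = self.entity_head.emissions(h)
                loss_entity = loss_entity + self.entity_head.nll(
                    em,
                    lengths[rows],
                    gold_tags[rows],
                    np.stack([s_ent_mask[chunk[i]] for i in rows]),
                )
                bd.n_entity_tokens += int(lengths[rows].sum())

        # --- attribute task: gold segments, entity-restricted label space
        a_ids, a_gold, a_mask = [], [], []
        attr_index = {lab: i for i, lab in enumerate(self.attr_labels)}
        for doc in docs if "attr" in active else []:
            for ei, ent in enumerate(doc.entities):
                spans = [
                    Span(a.label, a.start, a.end)
                    for a in doc.attributes
                    if a.entity_index == ei
                ]
                start, end = ent.start, ent.end
                if self._drop_rng is not None:
                    # boundary-jitter augmentation: the upstream segment head
                    # may slip by a character, and attribute decoding should
                    # not care as long as the attribute characters survive
                    lo = min((s.start for s in spans), default=start)
                    hi = max((s.end for s in spans), default=end)
                    start = min(
                        max(0, start + int(self._drop_rng.integers(-1, 2))), lo
                    )
                    end = max(
                        min(len(doc.corrected_text), end + int(self._drop_rng.integers(-1, 2))),
                        hi,
                    )
                seq = char_tokenize(
                    doc.corrected_text[start:end], base_offset=start
                )
                if len(seq) == 0:
                    continue
                ids = self._ids(seq.chars)
                tags = bio_encode(spans, seq)[: len(ids)]
                a_ids.append(ids)
                a_gold.append(np.array([attr_index[t] for t in tags], dtype=int))
                a_mask.append(self._attr_mask(ent.label))
        loss_attr = Tensor(0.0)
        for chunk in _length_chunks([len(s) for s in a_ids]) if a_ids else []:
            ids, gold, lengths = _pad_batch(
                [a_ids[i] for i in chunk], [a_gold[i] for i in chunk]
            )
            ctx, _ = self.encoder(ids, lengths, drop_rng=self._drop_rng)
            h = self.attr_rnn(ctx)
            em = self.attr_head.emissions(h)
            loss_attr = loss_attr + self.attr_head.nll(
                em, lengths, gold, np.stack([a_mask[i] for i in chunk])
            )
            bd.n_attr_tokens += int(lengths.sum())

        total = loss_punct + loss_entity + loss_attr + loss_cls
        if self.cfg.reduction == "mean":
            denom = max(
                1,
                bd.m_punct_tokens
                + bd.n_entity_tokens
                + bd.n_attr_tokens
                + bd.h_sentences,
            )
            total = total * (1.0 / denom)
            bd.loss_punct = float(loss_punct.data) / denom
            bd.loss_entity = float(loss_entity.data) / denom
            bd.loss_attr = float(loss_attr.data) / denom
            bd.loss_cls = float(loss_cls.data) / denom
        else:
            bd.loss_punct = float(loss_punct.data)
            bd.loss_entity = float(loss_entity.data)
            bd.loss_attr = float(loss_attr.data)
            bd.loss_cls = float(loss_cls.data)
        return total, bd

    # --------------------------------------------------------------- inference
    def _encode_one(self, chars: Sequence[str]) -> tuple[Tensor, Tensor]:
        ids = self._ids(chars)[None, :]
        return self.encoder(ids, np.array([ids.shape[1]]))

    def punct_forward(self, raw: CharSequence) -> list[str]:
        """Correct the punctuation of raw document text.

        Returns one tag per *non-punctuation* character: the mark that should
        follow it (or NONE).  The raw text's own marks are consumed as side
        features, so the head corrects misused marks rather than restoring
        punctuation from scratch.
        """
        stripped = strip_punctuation(raw, self.punct_space)
        if len(stripped) == 0:
            return []
        punct_index = {lab: i for i, lab in enumerate(self.punct_space.labels)}
        raw_tags = punct_targets(raw, raw, self.punct_space)
        ids = self._ids(stripped.chars)[None, :]
        feats = np.array([[punct_index[t] for t in raw_tags[: ids.shape[1]]]])
        ctx, _ = self.encoder(ids, np.array([ids.shape[1]]), feat_ids=feats)
        em = self.punct_head.emissions(ctx).data[0]
        return self.punct_head.decode(em, set(self.punct_space.labels))

    def classify_sentence(self, sent: CharSequence) -> tuple[str, np.ndarray]:
        _, summary = self._encode_one(sent.chars)
        logits = (
            summary @ self.cls_params["cls.w"] + self.cls_params["cls.b"]
        ).data[0]
        e = np.exp(logits - logits.max())
        probs = e / e.sum()
        return self.class_labels[int(np.argmax(logits))], probs

    def entity_forward(self, sent: CharSequence, cls: str) -> list[str]:
        """BIO tags over the entity label space of ``cls``."""
        if not sm.entities_for_class(self.schema, cls) or len(sent) == 0:
            return ["O"] * len(sent)
        ctx, _ = self._encode_one(sent.chars)
        em = self.entity_head.emissions(self.entity_rnn(ctx)).data[0]
        allowed = {
            lab
            for lab, ok in zip(self.entity_labels, self._entity_mask(cls))
            if ok
        }
        return self.entity_head.decode(em, allowed)

    def attr_forward(self, segment: CharSequence, entity: str) -> list[str]:
        """BIO tags over the attribute label space of ``entity``."""
        if len(segment) == 0:
            return []
        sm.attributes_for(self.schema, entity)  # raises on unknown entity
        ctx, _ = self._encode_one(segment.chars)
        em = self.attr_head.emissions(self.attr_rnn(ctx)).data[0]
        allowed = {
            lab for lab, ok in zip(self.attr_labels, self._attr_mask(entity)) if ok
        }
        return self.attr_head.decode(em, allowed)


# --------------------------------------------------------------------- bundle


@dataclass
class ModelBundle:
    """A trained model plus everything needed to reload and rerun it."""

    model: MultiTaskModel
    train_config: TrainConfig
    training_log: list[LossBreakdown] = field(default_factory=list)

    @property
    def schema(self) -> sm.Schema:
        return self.model.schema

    @property
    def fingerprint(self) -> str:
        blob = json.dumps(
            {
                "model": self.model.cfg.model_dump(),
                "train": self.train_config.model_dump(),
                "schema": self.model.schema.model_dump(),
                "vocab": self.model.vocab.chars,
            },
            sort_keys=True,
            ensure_ascii=False,
        )
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "fingerprint": self.fingerprint,
            "model_config": self.model.cfg.model_dump(),
            "train_config": self.train_config.model_dump(),
            "schema": self.model.schema.model_dump(),
            "vocab": self.model.vocab.chars,
            "training_log": [vars(b) for b in self.training_log],
        }
        (out / "bundle.json").write_text(
            json.dumps(meta, ensure_ascii=False, indent=1), encoding="utf-8"
        )
        params = {k: v.data for k, v in self.model.named_params().items()}
        np.savez(out / "params.npz", **params)

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModelBundle":
        out = Path(in_dir)
        meta = json.loads((out / "bundle.json").read_text(encoding="utf-8"))
        schema = sm.Schema.model_validate(meta["schema"])
        vocab = Vocab(meta["vocab"])
        model = MultiTaskModel(schema, vocab, ModelConfig(**meta["model_config"]))
        with np.load(out / "params.npz") as arch:
            for k, t in model.named_params().items():
                t.data[...] = arch[k]
        bundle = cls(
            model=model,
            train_config=TrainConfig(**meta["train_config"]),
            training_log=[LossBreakdown(**b) for b in meta["training_log"]],
        )
        if bundle.fingerprint != meta["fingerprint"]:
            raise ValueError("bundle fingerprint mismatch")
        return bundle

    # thin delegation so callers can treat the bundle as the model
    def __getattr__(self, name):
        return getattr(self.model, name)


# -------------------------------------------------------------------- training


def train(
    corpus: Sequence[AnnotatedDocument],
    schema: sm.Schema,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    log_every: int = 0,
) -> ModelBundle:
    """Jointly train all four heads on a fully annotated corpus.

    Deterministic given the seeds in the configs: parameter init comes from
    ``model_config.seed``, batch shuffling from ``train_config.seed``.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    for doc in corpus:
        doc.validate(schema)
    vocab = Vocab.from_texts(
        [d.text for d in corpus] + [d.corrected_text for d in corpus]
    )
    model = MultiTaskModel(schema, vocab, model_config)
    params = model.named_params()
    opt = Adam(list(params.values()), lr=train_config.lr)
    shuffle_rng = np.random.default_rng(train_config.seed + 1)
    model._drop_rng = np.random.default_rng(train_config.seed + 3)
    order = np.arange(len(corpus))
    log: list[LossBreakdown] = []
    if train_config.schedule == "staged":
        # one task after another, epochs split as evenly as possible
        per = [train_config.epochs // 4] * 4
        for i in range(train_config.epochs % 4):
            per[i] += 1
        epoch_tasks = [
            (task,) for task, n in zip(MultiTaskModel.TASKS, per) for _ in range(n)
        ]
    else:
        epoch_tasks = [None] * train_config.epochs
    for epoch, tasks in enumerate(epoch_tasks):
        opt.lr = train_config.lr_at(epoch)
        shuffle_rng.shuffle(order)
        epoch_bd = LossBreakdown()
        for lo in range(0, len(corpus), train_config.batch_size):
            batch = [corpus[i] for i in order[lo : lo + train_config.batch_size]]
            total, bd = model.joint_loss(batch, tasks=tasks)
            if not np.isfinite(total.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: {vars(bd)}"
                )
            # summed-joint-loss additivity must hold exactly on every batch
            parts = bd.loss_punct + bd.loss_entity + bd.loss_attr + bd.loss_cls
            assert abs(float(total.data) - parts) < 1e-8 * max(1.0, abs(parts))
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_bd = epoch_bd + bd
        log.append(epoch_bd)
        if log_every and (epoch + 1) % log_every == 0:
            print(
                f"epoch {epoch + 1}/{train_config.epochs} "
                f"loss_total={epoch_bd.loss_total:.2f} "
                f"(punct={epoch_bd.loss_punct:.2f} ent={epoch_bd.loss_entity:.2f} "
                f"attr={epoch_bd.loss_attr:.2f} cls={epoch_bd.loss_cls:.2f})"
            )
    model._drop_rng = None  # back to inference mode
    return ModelBundle(model=model, train_config=train_config, training_log=log)
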