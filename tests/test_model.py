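"""Joint loss additivity, determinism, CRF/cross-entropy equivalence, bundles."""

import copy

import numpy as np
import pytest

from mlee import crf as crf_mod
from mlee.model import (
    LossBreakdown,
    ModelBundle,
    ModelConfig,
    MultiTaskModel,
    TrainConfig,
    Vocab,
    train,
)
from mlee.seqlabels import char_tokenize
from mlee.synth import GeneratorConfig, generate_corpus

TINY = ModelConfig(embed_dim=32, ffn_dim=48, rnn_dim=16, n_layers=1, seed=5)


def _model(corpus, schema, cfg=TINY):
    vocab = Vocab.from_texts(
        [d.text for d in corpus] + [d.corrected_text for d in corpus]
    )
    return MultiTaskModel(schema, vocab, cfg)


def test_joint_loss_additivity_and_linearity(tiny_corpus, schema):
    model = _model(tiny_corpus, schema)
    batch = tiny_corpus[:4]
    total, bd = model.joint_loss(batch)
    parts = bd.loss_punct + bd.loss_entity + bd.loss_attr + bd.loss_cls
    assert abs(float(total.data) - parts) < 1e-8 * max(1.0, abs(parts))
    assert bd.loss_seq_total == pytest.approx(
        bd.loss_punct + bd.loss_entity + bd.loss_attr, abs=1e-12
    )
    # Σ-form (sum reduction): a duplicated batch doubles every component
    total2, bd2 = model.joint_loss(batch + batch)
    for name in ("loss_punct", "loss_entity", "loss_attr", "loss_cls"):
        assert getattr(bd2, name) == pytest.approx(2 * getattr(bd, name), rel=1e-9)
    # ... and the batch loss is the sum of singleton losses
    singles = sum(float(model.joint_loss([d])[0].data) for d in batch)
    assert float(total.data) == pytest.approx(singles, rel=1e-9)


def test_joint_loss_counts_tasks_separately(tiny_corpus, schema):
    model = _model(tiny_corpus, schema)
    doc = copy.deepcopy(tiny_corpus[0])
    doc.entities, doc.attributes = [], []
    for i, s in enumerate(doc.sentences):
        doc.sentences[i] = type(s)(s.start, s.end, "Other")
    _, bd = model.joint_loss([doc])
    assert bd.loss_entity == 0.0 and bd.loss_attr == 0.0
    assert bd.loss_cls > 0.0 and bd.loss_punct > 0.0
    assert bd.n_entity_tokens == 0 and bd.h_sentences == len(doc.sentences)


def test_crf_off_equals_per_token_cross_entropy(tiny_corpus, schema):
    """With zero transitions the sequence NLL is the summed token NLL."""
    cfg = TINY.model_copy(update={"crf": "off"})
    model = _model(tiny_corpus, schema, cfg)
    doc = tiny_corpus[0]
    _, bd = model.joint_loss([doc])
    # independent recomputation of the attribute-task loss, token by token
    expected = 0.0
    attr_index = {lab: i for i, lab in enumerate(model.attr_labels)}
    from mlee.seqlabels import Span, bio_encode

    for ei, ent in enumerate(doc.entities):
        seq = char_tokenize(
            doc.corrected_text[ent.start : ent.end], base_offset=ent.start
        )
        ctx, _ = model._encode_one(seq.chars)
        em = model.attr_head.emissions(model.attr_rnn(ctx)).data[0]
        em = np.where(model._attr_mask(ent.label)[None, :], em, -1e30)
        spans = [
            Span(a.label, a.start, a.end)
            for a in doc.attributes
            if a.entity_index == ei
        ]
        gold = [attr_index[t] for t in bio_encode(spans, seq)]
        for t, g in enumerate(gold):
            row = em[t]
            expected += float(np.log(np.exp(row - row.max()).sum()) + row.max() - row[g])
    assert bd.loss_attr == pytest.approx(expected, rel=1e-8)


def test_encoder_determinism_and_position_sensitivity(tiny_corpus, schema):
    model = _model(tiny_corpus, schema)
    seq = char_tokenize("发热2天")
    c1, s1 = model._encode_one(seq.chars)
    c2, s2 = model._encode_one(seq.chars)
    assert np.array_equal(c1.data, c2.data) and np.array_equal(s1.data, s2.data)
    c3, _ = model._encode_one(tuple("热发2天"))  # swapped characters
    assert not np.allclose(c1.data, c3.data)
    # empty input still yields a summary vector and zero context positions
    c0, s0 = model._encode_one(())
    assert c0.data.shape[1] == 0 and s0.data.shape[-1] == TINY.embed_dim


def test_classifier_probabilities_sum_to_one(tiny_bundle):
    _, probs = tiny_bundle.model.classify_sentence(char_tokenize("患儿发热。"))
    assert probs.sum() == pytest.approx(1.0, abs=1e-6)
    assert (probs >= 0).all()


def test_masked_labels_never_decoded(tiny_bundle, schema):
    """Class-conditioned masking: only the class's entities can be decoded."""
    model = tiny_bundle.model
    sent = char_tokenize("患儿3天前出现发热，体温38.5℃。")
    for cls in ("Symptom", "Treatment", "Imaging", "Laboratory Test"):
        from mlee.schema import entities_for_class

        allowed = set(entities_for_class(schema, cls))
        tags = model.entity_forward(sent, cls)
        labels = {t[2:] for t in tags if t != "O"}
        assert labels <= allowed
    assert model.entity_forward(sent, "Other") == ["O"] * len(sent)


def test_train_smoke_and_seed_determinism(schema):
    corpus = generate_corpus(GeneratorConfig(n_documents=10, seed=9))
    tc = TrainConfig(epochs=2, batch_size=5, seed=9)
    b1 = train(corpus, schema, TINY, tc)
    assert all(np.isfinite(e.loss_total) for e in b1.training_log)
    assert b1.training_log[-1].loss_total < b1.training_log[0].loss_total
    b2 = train(corpus, schema, TINY, tc)
    for k, v in b1.model.named_params().items():
        assert np.array_equal(v.data, b2.model.named_params()[k].data), k


def test_bundle_roundtrip_is_bit_identical(tiny_bundle, tmp_path):
    tiny_bundle.save(tmp_path / "bundle")
    loaded = ModelBundle.load(tmp_path / "bundle")
    assert loaded.fingerprint == tiny_bundle.fingerprint
    sent = char_tokenize("昨日发热，体温39.2℃。")
    assert loaded.model.punct_forward(sent) == tiny_bundle.model.punct_forward(sent)
    c1, _ = tiny_bundle.model.classify_sentence(sent)
    c2, _ = loaded.model.classify_sentence(sent)
    assert c1 == c2
    for k, v in tiny_bundle.model.named_params().items():
        assert np.array_equal(v.data, loaded.model.named_params()[k].data)


def test_task_filter_zeroes_excluded_components(tiny_corpus, schema):
    model = _model(tiny_corpus, schema)
    batch = tiny_corpus[:3]
    _, full = model.joint_loss(batch)
    for task, attr in [
        ("punct", "loss_punct"),
        ("cls", "loss_cls"),
        ("entity", "loss_entity"),
        ("attr", "loss_attr"),
    ]:
        total, bd = model.joint_loss(batch, tasks=[task])
        assert getattr(bd, attr) == pytest.approx(getattr(full, attr), rel=1e-9)
        others = bd.loss_total - getattr(bd, attr)
        assert others == 0.0
    with pytest.raises(ValueError):
        model.joint_loss(batch, tasks=["nope"])


def test_staged_training_smoke(schema):
    corpus = generate_corpus(GeneratorConfig(n_documents=8, seed=11))
    tc = TrainConfig(epochs=4, batch_size=4, seed=11, schedule="staged")
    bundle = train(corpus, schema, TINY, tc)
    logs = bundle.training_log
    assert len(logs) == 4
    # phase epochs exercise exactly one task each, in cascade order
    assert logs[0].loss_punct > 0 and logs[0].loss_cls == 0
    assert logs[1].loss_cls > 0 and logs[1].loss_punct == 0
    assert logs[2].loss_entity > 0 and logs[3].loss_attr > 0


def test_overlength_input_truncated_with_warning(tiny_corpus, schema):
    cfg = TINY.model_copy(update={"max_len": 8})
    model = _model(tiny_corpus, schema, cfg)
    with pytest.warns(UserWarning, match="truncated"):
        tags = model.punct_forward(char_tokenize("发热咳嗽发热咳嗽发热咳嗽"))
    assert len(tags) == 8
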