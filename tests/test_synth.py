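"""Synthetic-corpus generator: validity, determinism, statistical fidelity."""

import numpy as np
import pytest

from mlee.corpus import read_jsonl, write_jsonl
from mlee.synth import (
    GeneratorConfig,
    corpus_stats,
    corrupt_punctuation,
    default_template_bank,
    generate_corpus,
)


def test_every_document_validates(schema, tiny_corpus):
    for doc in tiny_corpus:
        doc.validate(schema)  # raises on any layer inconsistency


def test_seed_determinism(schema):
    cfg = GeneratorConfig(n_documents=15, seed=21)
    a = generate_corpus(cfg, schema)
    b = generate_corpus(cfg, schema)
    assert [d.to_dict() for d in a] == [d.to_dict() for d in b]
    c = generate_corpus(cfg.model_copy(update={"seed": 22}), schema)
    assert [d.to_dict() for d in a] != [d.to_dict() for d in c]


def test_corruption_rate_extremes(schema):
    clean = generate_corpus(GeneratorConfig(n_documents=10, corruption_rate=0.0, seed=1))
    assert all(d.text == d.corrected_text for d in clean)
    dirty = generate_corpus(GeneratorConfig(n_documents=10, corruption_rate=1.0, seed=1))
    assert all("。" not in d.text for d in dirty)
    assert corpus_stats(dirty).corruption_rate == 1.0


def test_corrupt_punctuation_single_site():
    rng = np.random.default_rng(0)
    assert corrupt_punctuation("A。B。", 0.0, rng) == "A。B。"
    out = corrupt_punctuation("A。B。", 1.0, np.random.default_rng(0))
    assert out == "A，B，"


def test_corruption_count_is_binomial():
    rng = np.random.default_rng(5)
    text = "体温高。" * 2500  # 10^4 marks across repeated sentences
    corrupted = corrupt_punctuation(text * 4, 0.5, rng)
    n = corrupted.count("，")
    n_marks = 10_000
    sigma = np.sqrt(n_marks * 0.25)
    assert abs(n - 5000) < 3 * sigma


def test_default_config_matches_clinical_conditions(schema):
    """The default corpus reproduces the emulated corpus-level statistics."""
    docs = generate_corpus(GeneratorConfig(n_documents=300, seed=7), schema)
    st = corpus_stats(docs)
    assert abs(st.attributes_per_entity - 2.82) < 0.2
    p = 0.486
    se = np.sqrt(p * (1 - p) / st.n_sentence_final_marks)
    assert abs(st.corruption_rate - p) < 3 * se
    # realized class mixture tracks the configured mixture
    mix = GeneratorConfig().class_mixture
    for cls, weight in mix.items():
        frac = st.class_counts.get(cls, 0) / st.n_sentences
        assert abs(frac - weight) < 0.05


def test_corpus_stats_counts(schema):
    docs = generate_corpus(GeneratorConfig(n_documents=5, seed=2), schema)
    st = corpus_stats(docs)
    assert st.n_sentences == sum(len(d.sentences) for d in docs)
    assert st.n_entities == sum(len(d.entities) for d in docs)
    assert st.attributes_per_entity == pytest.approx(
        st.n_attributes / st.n_entities
    )
    assert corpus_stats([]).n_sentences == 0


def test_template_bank_slots_stay_inside_schema(schema):
    import copy

    from mlee.synth import TemplateBank

    bank = default_template_bank()
    bank.validate(schema)  # raises on a stray slot
    templates = copy.deepcopy(bank.templates)
    templates["Fever"].append("体温{Value}")  # Value belongs to lab tests
    bad = TemplateBank(templates, bank.lexicons, bank.other_sentences)
    with pytest.raises(ValueError, match="Value"):
        bad.validate(schema)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(class_mixture={"Symptom": 0.5})
    with pytest.raises(ValueError):
        GeneratorConfig(corruption_rate=1.5)


def test_jsonl_roundtrip(tmp_path, tiny_corpus):
    path = tmp_path / "c.jsonl"
    write_jsonl(tiny_corpus, path)
    back = read_jsonl(path)
    assert [d.to_dict() for d in back] == [d.to_dict() for d in tiny_corpus]
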