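"""Schema hierarchy: label spaces, flattening, validation."""

import pytest

from mlee import schema as sm


def test_default_schema_shape(schema):
    labels = sm.sentence_label_set(schema)
    assert labels == ["Symptom", "Treatment", "Laboratory Test", "Imaging", "Other"]
    assert sm.entities_for_class(schema, "Symptom") == ["Fever", "Cough"]
    assert sm.entities_for_class(schema, "Imaging") == [
        "Computed Tomography",
        "Magnetic Resonance Imaging",
    ]
    assert sm.entities_for_class(schema, "Other") == []


@pytest.mark.parametrize(
    "entity, expected",
    [
        ("Fever", ["Body Temperature", "Occurrence", "Duration"]),
        ("Laboratory Test Entity", ["Test item", "Value"]),
        (
            "Magnetic Resonance Imaging",
            ["Body part", "Abnormal seen", "T1WI", "T2WI"],
        ),
    ],
)
def test_attributes_for(schema, entity, expected):
    assert sm.attributes_for(schema, entity) == expected


def test_flatten_default_schema(schema):
    flat = sm.flatten(schema)
    assert len(flat) == 23  # (3+6) + (3+3) + 2 + (2+4) per entity, enumerated
    texts = [f.text for f in flat]
    assert "Medication Treatment-Drug dose" in texts
    assert len(set(texts)) == len(texts)


def test_flatten_is_lossless(schema):
    pairs = {
        (ent, attr)
        for et in schema.entity_types
        for e in et.entities
        for ent, attr in [(e.name, a) for a in e.attributes]
    }
    recovered = {
        (sm.FlatLabel.parse(f.text, schema).entity, sm.FlatLabel.parse(f.text, schema).attribute)
        for f in sm.flatten(schema)
    }
    assert recovered == pairs


def test_classes_partition_entities(schema):
    all_entities = set(schema.entity_names())
    union = set()
    for cls in sm.sentence_label_set(schema):
        ents = set(sm.entities_for_class(schema, cls))
        assert not (union & ents)  # classes are disjoint
        union |= ents
    assert union == all_entities


def test_attributes_consistent_with_flatten(schema):
    for ent in schema.entity_names():
        via_flat = [f.attribute for f in sm.flatten(schema) if f.entity == ent]
        assert via_flat == sm.attributes_for(schema, ent)


def test_duplicate_entity_rejected():
    with pytest.raises(sm.SchemaError, match="Fever"):
        sm._coerce(
            {
                "entity_types": [
                    {"name": "A", "entities": [{"name": "Fever", "attributes": []}]},
                    {"name": "B", "entities": [{"name": "Fever", "attributes": []}]},
                ]
            }
        )


def test_minimal_schema_valid_and_degenerate_label_sets():
    minimal = sm._coerce(
        {"entity_types": [{"name": "T", "entities": [{"name": "E", "attributes": []}]}]}
    )
    assert sm.sentence_label_set(minimal) == ["T", "Other"]
    assert sm.flatten(minimal) == []  # zero-attribute entity contributes nothing
    empty = sm._coerce({"entity_types": []})
    assert sm.sentence_label_set(empty) == ["Other"]


def test_load_schema_roundtrip(tmp_path, schema):
    import yaml

    path = tmp_path / "s.yaml"
    path.write_text(
        yaml.safe_dump(schema.model_dump(), allow_unicode=True), encoding="utf-8"
    )
    loaded = sm.load_schema(path)
    assert loaded.model_dump() == schema.model_dump()


def test_unknown_lookups_raise(schema):
    with pytest.raises(sm.SchemaError):
        sm.entities_for_class(schema, "Nope")
    with pytest.raises(sm.SchemaError):
        sm.attributes_for(schema, "Nope")
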