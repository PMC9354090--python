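"""Label-hierarchy schema: entity types -> entities -> attributes.

The schema drives every stage of the cascade: entity-type names (plus the
reserved ``Other`` class) form the sentence-classification label set, entity
names form the segment-tagging label space (restricted per sentence class),
and attribute names form the attribute-tagging label space (restricted per
entity).  ``flatten`` produces the Cartesian ``<entity>-<attribute>`` label
set used by the single-stage baseline tagger.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
import yaml
from pydantic import BaseModel, field_validator, model_validator

OTHER_CLASS = "Other"

__all__ = [
    "OTHER_CLASS",
    "Schema",
    "EntityTypeDef",
    "EntityDef",
    "FlatLabel",
    "SchemaError",
    "load_schema",
    "default_schema",
    "sentence_label_set",
    "entities_for_class",
    "attributes_for",
    "flatten",
]


class SchemaError(ValueError):
    """Schema failed validation or a lookup referenced an unknown element."""


class EntityDef(BaseModel):
    name: str
    attributes: list[str] = []

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("entity name must be non-empty")
        return v

    @field_validator("attributes")
    @classmethod
    def _attrs_unique(cls, v: list[str]) -> list[str]:
        if any(not a.strip() for a in v):
            raise ValueError("attribute names must be non-empty")
        if len(set(v)) != len(v):
            dup = sorted({a for a in v if v.count(a) > 1})
            raise ValueError(f"duplicate attribute names {dup}")
        return v


class EntityTypeDef(BaseModel):
    name: str
    entities: list[EntityDef] = []

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("entity-type name must be non-empty")
        return v

    @model_validator(mode="after")
    def _entities_allowed(self) -> "EntityTypeDef":
        if not self.entities and self.name != OTHER_CLASS:
            raise ValueError(
                f"entity type {self.name!r} has no entities "
                f"(only the reserved {OTHER_CLASS!r} type may be empty)"
            )
        return self


class Schema(BaseModel):
    entity_types: list[EntityTypeDef] = []
    version: str = ""

    @model_validator(mode="after")
    def _validate_hierarchy(self) -> "Schema":
        seen_types: set[str] = set()
        seen_entities: dict[str, str] = {}
        for et in self.entity_types:
            if et.name in seen_types:
                raise ValueError(f"duplicate entity type {et.name!r}")
            seen_types.add(et.name)
            for ent in et.entities:
                if ent.name in seen_entities:
                    raise ValueError(
                        f"entity {ent.name!r} appears under both "
                        f"{seen_entities[ent.name]!r} and {et.name!r}"
                    )
                seen_entities[ent.name] = et.name
        return self

    # -- convenience wrappers over the module-level operations ---------------
    def sentence_labels(self) -> list[str]:
        return sentence_label_set(self)

    def entity_names(self) -> list[str]:
        return [e.name for et in self.entity_types for e in et.entities]

    def attribute_names(self) -> list[str]:
        """Unique attribute names in first-appearance (document) order."""
        out: list[str] = []
        for et in self.entity_types:
            for ent in et.entities:
                for a in ent.attributes:
                    if a not in out:
                        out.append(a)
        return out


class FlatLabel(BaseModel):
    """One ``<entity>-<attribute>`` label of the flattened baseline space."""

    entity: str
    attribute: str

    @property
    def text(self) -> str:
        return f"{self.entity}-{self.attribute}"

    @classmethod
    def parse(cls, text: str, schema: Schema) -> "FlatLabel":
        """Invert ``text`` against ``schema`` (entity names may contain '-')."""
        for ent in schema.entity_names():
            prefix = ent + "-"
            if text.startswith(prefix):
                attr = text[len(prefix):]
                if attr in attributes_for(schema, ent):
                    return cls(entity=ent, attribute=attr)
        raise SchemaError(f"flat label {text!r} does not match the schema")


def _coerce(data: dict) -> Schema:
    try:
        schema = Schema.model_validate(data)
    except Exception as exc:  # pydantic ValidationError carries the element name
        raise SchemaError(str(exc)) from exc
    if OTHER_CLASS not in {et.name for et in schema.entity_types}:
        schema.entity_types.append(EntityTypeDef(name=OTHER_CLASS, entities=[]))
    return schema


def load_schema(path: str | Path) -> Schema:
    """Load and validate a schema from a YAML or JSON file.

    The reserved ``Other`` sentence class is appended if absent.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"schema file not found: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except Exception as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"schema file {path} must contain a mapping")
    return _coerce(data)


def default_schema() -> Schema:
    """The bundled default: four clinical entity types plus ``Other``."""
    text = (
        resources.files("mlee").joinpath("data/default_schema.yaml").read_text("utf-8")
    )
    return _coerce(yaml.safe_load(text))


def sentence_label_set(schema: Schema) -> list[str]:
    """Entity-type names plus ``Other``, in schema document order."""
    labels = [et.name for et in schema.entity_types if et.name != OTHER_CLASS]
    labels.append(OTHER_CLASS)
    return labels


def entities_for_class(schema: Schema, class_name: str) -> list[str]:
    """Entity labels decodable inside sentences of ``class_name``.

    Empty for the reserved ``Other`` class.
    """
    for et in schema.entity_types:
        if et.name == class_name:
            return [e.name for e in et.entities]
    if class_name == OTHER_CLASS:
        return []
    raise SchemaError(f"unknown sentence class {class_name!r}")


def attributes_for(schema: Schema, entity_name: str) -> list[str]:
    """Attribute label space used when tagging inside a segment of ``entity_name``."""
    for et in schema.entity_types:
        for ent in et.entities:
            if ent.name == entity_name:
                return list(ent.attributes)
    raise SchemaError(f"unknown entity {entity_name!r}")


def entity_type_of(schema: Schema, entity_name: str) -> str:
    for et in schema.entity_types:
        for ent in et.entities:
            if ent.name == entity_name:
                return et.name
    raise SchemaError(f"unknown entity {entity_name!r}")


def flatten(schema: Schema) -> list[FlatLabel]:
    """One flat label per (entity, attribute) pair, in schema order."""
    return [
        FlatLabel(entity=ent.name, attribute=attr)
        for et in schema.entity_types
        for ent in et.entities
        for attr in ent.attributes
    ]
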