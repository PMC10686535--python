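"""Information model for radiology-report structuring.

The model distinguishes two *concept* entity types — observations (directly
seen imaging features such as "nodule" or "pleural effusion") and clinical
findings (interpretations such as "lung cancer") — and five *modifier*
entity types that attach attributes to a concept: anatomical location,
certainty, change, characteristics and size.

Two directed relation types connect entities:

* ``MODIFIER``: concept (observation or clinical finding) -> modifier entity.
* ``EVIDENCE``: observation -> the clinical finding it supports.

Every other module validates its entities and relations against this schema.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class SchemaError(ValueError):
    """An entity or relation violates the information model."""


class EntityCategory(enum.Enum):
    CONCEPT = "concept"
    MODIFIER = "modifier"


class EntityType(enum.Enum):
    """The 7 entity types of the information model."""

    OBSERVATION = "Observation"
    CLINICAL_FINDING = "Clinical_finding"
    ANATOMICAL_LOCATION = "Anatomical_location"
    CERTAINTY = "Certainty"
    CHANGE = "Change"
    CHARACTERISTICS = "Characteristics"
    SIZE = "Size"

    @property
    def brat_label(self) -> str:
        """Type name as written in BRAT .ann files (1:1 mapping)."""
        return self.value

    @property
    def category(self) -> EntityCategory:
        if self in (EntityType.OBSERVATION, EntityType.CLINICAL_FINDING):
            return EntityCategory.CONCEPT
        return EntityCategory.MODIFIER

    @classmethod
    def from_label(cls, label: str) -> "EntityType":
        for member in cls:
            if member.value == label or member.name == label:
                return member
        raise SchemaError(f"unknown entity type name: {label!r}")


CONCEPT_TYPES = frozenset(
    {EntityType.OBSERVATION, EntityType.CLINICAL_FINDING}
)
MODIFIER_TYPES = frozenset(
    {
        EntityType.ANATOMICAL_LOCATION,
        EntityType.CERTAINTY,
        EntityType.CHANGE,
        EntityType.CHARACTERISTICS,
        EntityType.SIZE,
    }
)


class RelationType(enum.Enum):
    """Directed relation types with head/tail type constraints."""

    MODIFIER = "Modifier"
    EVIDENCE = "Evidence"

    @property
    def brat_label(self) -> str:
        return self.value

    @property
    def head_types(self) -> frozenset[EntityType]:
        if self is RelationType.MODIFIER:
            return CONCEPT_TYPES
        return frozenset({EntityType.OBSERVATION})

    @property
    def tail_types(self) -> frozenset[EntityType]:
        if self is RelationType.MODIFIER:
            return MODIFIER_TYPES
        return frozenset({EntityType.CLINICAL_FINDING})

    @classmethod
    def from_label(cls, label: str) -> "RelationType":
        for member in cls:
            if member.value == label or member.name == label:
                return member
        raise SchemaError(f"unknown relation type name: {label!r}")


def validate_relation(
    head_type: EntityType, tail_type: EntityType, rel_type: RelationType
) -> bool:
    """Return True iff (head_type, tail_type) is admissible for rel_type.

    A modifier relation runs from a concept (observation or clinical
    finding) to one of the 5 modifier types; an evidence relation runs
    from an observation to a clinical finding.  Of the 7x7x2 ordered type
    combinations exactly 11 are admissible.
    """
    if not isinstance(head_type, EntityType) or not isinstance(tail_type, EntityType):
        raise SchemaError("head_type and tail_type must be EntityType members")
    if not isinstance(rel_type, RelationType):
        raise SchemaError("rel_type must be a RelationType member")
    return head_type in rel_type.head_types and tail_type in rel_type.tail_types


@dataclass
class EntitySpan:
    """A typed mention anchored at 0-based, half-open character offsets."""

    id: str
    type: EntityType
    start: int
    end: int
    text: str

    def validate(self, report_text: str) -> None:
        if not (0 <= self.start < self.end <= len(report_text)):
            raise SchemaError(
                f"entity {self.id}: span [{self.start},{self.end}) outside "
                f"text of length {len(report_text)}"
            )
        actual = report_text[self.start : self.end]
        if actual != self.text:
            raise SchemaError(
                f"entity {self.id}: text {self.text!r} does not match "
                f"report substring {actual!r}"
            )

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Relation:
    """A directed, typed link between two entity spans of one report.

    ``score`` carries the classifier probability on predicted relations;
    it is ``None`` on gold annotations.
    """

    id: str
    type: RelationType
    head: EntitySpan
    tail: EntitySpan
    score: float | None = None

    def validate(self) -> None:
        if self.head is self.tail or (
            self.head.start == self.tail.start and self.head.end == self.tail.end
        ):
            raise SchemaError(f"relation {self.id}: head and tail are the same span")
        if not validate_relation(self.head.type, self.tail.type, self.type):
            raise SchemaError(
                f"relation {self.id}: ({self.head.type.name}, "
                f"{self.tail.type.name}) not admissible for {self.type.name}"
            )


def normalize_relation_direction(
    rel_type: RelationType, arg1: EntitySpan, arg2: EntitySpan
) -> tuple[EntitySpan, EntitySpan]:
    """Orient an argument pair as (head, tail) under the schema.

    Annotation files may list the arguments in either order; storage is
    always head->tail.  Raises :class:`SchemaError` if neither orientation
    is admissible.
    """
    if validate_relation(arg1.type, arg2.type, rel_type):
        return arg1, arg2
    if validate_relation(arg2.type, arg1.type, rel_type):
        return arg2, arg1
    raise SchemaError(
        f"no admissible orientation for {rel_type.name} between "
        f"{arg1.type.name} and {arg2.type.name}"
    )


def schema_config() -> dict:
    """Human-readable schema block mapping .ann type names to the model."""
    return {
        "entity_types": {
            t.brat_label: t.category.value for t in EntityType
        },
        "relation_types": {
            r.brat_label: {
                "head": sorted(t.brat_label for t in r.head_types),
                "tail": sorted(t.brat_label for t in r.tail_types),
            }
            for r in RelationType
        },
    }
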