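"""In-memory corpus containers: tokens, sentences, annotated reports."""

from __future__ import annotations

from dataclasses import dataclass, field

from .schema import EntitySpan, Relation, SchemaError


@dataclass
class Token:
    start: int
    end: int
    text: str


@dataclass
class Sentence:
    """A contiguous span of the report text with its tokenization.

    ``out_of_scope`` flags sentences that carry no clinical content under
    the information model (imaging technique, surgical procedure,
    recommendations); they are excluded from coverage computation.
    """

    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)
    out_of_scope: bool = False


@dataclass
class AnnotatedReport:
    """One report: text, sentence/token structure, entities and relations.

    The unit of I/O, training and evaluation.  ``source`` optionally tags
    the report origin (e.g. chest vs abdomen) for stratified splitting.
    """

    id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    entities: list[EntitySpan] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    source: str | None = None

    def validate(self) -> None:
        """Check every entity/relation invariant against this report."""
        ids = set()
        for ent in self.entities:
            ent.validate(self.text)
            if ent.id in ids:
                raise SchemaError(f"duplicate entity id {ent.id}")
            ids.add(ent.id)
        ent_set = {id(e) for e in self.entities}
        for rel in self.relations:
            rel.validate()
            if id(rel.head) not in ent_set or id(rel.tail) not in ent_set:
                raise SchemaError(
                    f"relation {rel.id}: endpoints not in this report's entities"
                )
        prev_end = -1
        for sent in self.sentences:
            if sent.start < prev_end:
                raise SchemaError("sentences overlap or are out of order")
            prev_end = sent.end
            t_prev = sent.start - 1
            for tok in sent.tokens:
                if tok.start < sent.start or tok.end > sent.end or tok.start <= t_prev:
                    if tok.start <= t_prev and tok.start >= sent.start:
                        raise SchemaError("tokens overlap or are out of order")
                    raise SchemaError("token outside its sentence span")
                t_prev = tok.end - 1

    def entity_by_id(self, eid: str) -> EntitySpan:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise KeyError(eid)

    def sentence_index_of(self, entity: EntitySpan) -> int:
        """Index of the sentence containing the entity (-1 if none)."""
        for i, sent in enumerate(self.sentences):
            if entity.start >= sent.start and entity.end <= sent.end:
                return i
        return -1
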