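"""IOB2 tag sequences: encoding entity spans to per-token tags and back.

The tag set is ``{O}`` plus ``B-<type>``/``I-<type>`` for each of the 7
entity types (15 tags).  ``B`` marks the first token of an entity, ``I``
subsequent tokens, ``O`` tokens outside any entity.  Overlapping entities
within one sentence cannot be represented and raise an error; invalid
tag sequences produced by a tagger are repaired at decode time with the
conlleval convention (an orphan ``I-t`` is promoted to ``B-t``).
"""

from __future__ import annotations

from .corpus import Sentence, Token
from .schema import EntitySpan, EntityType

#: Fixed tag order; index 0 is "O".  Tie-breaking in decoders uses this order.
TAGS: list[str] = ["O"]
for _t in EntityType:
    TAGS.append(f"B-{_t.brat_label}")
    TAGS.append(f"I-{_t.brat_label}")

TAG_TO_INDEX: dict[str, int] = {tag: i for i, tag in enumerate(TAGS)}


class Iob2Error(ValueError):
    pass


def _entities_in_sentence(
    sentence: Sentence, entities: list[EntitySpan]
) -> list[EntitySpan]:
    inside = [
        e for e in entities if e.start >= sentence.start and e.end <= sentence.end
    ]
    inside.sort(key=lambda e: (e.start, e.end))
    for a, b in zip(inside, inside[1:]):
        if b.start < a.end:
            raise Iob2Error(
                f"overlapping entities {a.id} and {b.id} cannot be encoded in IOB2"
            )
    return inside


def align_tokens(sentence: Sentence, entities: list[EntitySpan]) -> None:
    """Split tokens so every entity boundary falls on a token boundary.

    Gold spans are preserved exactly; a token straddling an entity
    boundary is split at that boundary (in place).
    """
    boundaries = set()
    for e in _entities_in_sentence(sentence, entities):
        boundaries.add(e.start)
        boundaries.add(e.end)
    new_tokens: list[Token] = []
    for tok in sentence.tokens:
        cuts = sorted(b for b in boundaries if tok.start < b < tok.end)
        if not cuts:
            new_tokens.append(tok)
            continue
        edges = [tok.start] + cuts + [tok.end]
        offset = tok.start
        for a, b in zip(edges, edges[1:]):
            new_tokens.append(Token(a, b, tok.text[a - offset : b - offset]))
    sentence.tokens = new_tokens


def encode_iob2(
    sentence: Sentence,
    entities: list[EntitySpan],
    split_misaligned: bool = True,
) -> list[str]:
    """Tag each token of ``sentence`` with IOB2 labels for ``entities``.

    Only entities fully inside the sentence span are considered.  With
    ``split_misaligned`` (the default) tokens straddling an entity
    boundary are first split so the gold span is representable; otherwise
    misalignment raises :class:`Iob2Error`.
    """
    inside = _entities_in_sentence(sentence, entities)
    if split_misaligned:
        align_tokens(sentence, entities)
    tags = []
    for tok in sentence.tokens:
        tag = "O"
        for ent in inside:
            if tok.start >= ent.start and tok.end <= ent.end:
                prefix = "B" if tok.start == ent.start else "I"
                tag = f"{prefix}-{ent.type.brat_label}"
                break
            if tok.start < ent.end and ent.start < tok.end:
                raise Iob2Error(
                    f"token [{tok.start},{tok.end}) straddles entity "
                    f"{ent.id} [{ent.start},{ent.end})"
                )
        tags.append(tag)
    return tags


def repair_tags(tags: list[str]) -> list[str]:
    """Promote orphan I-t tags (after O, start, or a different type) to B-t."""
    repaired = []
    prev_type = None
    for tag in tags:
        if tag.startswith("I-"):
            ttype = tag[2:]
            if prev_type != ttype:
                tag = "B-" + ttype
            prev_type = ttype
        elif tag.startswith("B-"):
            prev_type = tag[2:]
        else:
            prev_type = None
        repaired.append(tag)
    return repaired


def decode_iob2(
    text: str, sentence: Sentence, tags: list[str], id_prefix: str = "T"
) -> list[EntitySpan]:
    """Convert a tag sequence back into entity spans with char offsets.

    ``tags`` must have one tag per token.  Invalid sequences are repaired
    first (:func:`repair_tags`); maximal B-I runs of one type become one
    entity whose text is the exact report substring.
    """
    if len(tags) != len(sentence.tokens):
        raise Iob2Error(
            f"{len(tags)} tags for {len(sentence.tokens)} tokens"
        )
    tags = repair_tags(tags)
    entities: list[EntitySpan] = []
    run_start: int | None = None
    run_end = 0
    run_type: str | None = None

    def flush() -> None:
        nonlocal run_start, run_type
        if run_start is not None:
            entities.append(
                EntitySpan(
                    id=f"{id_prefix}{len(entities) + 1}",
                    type=EntityType.from_label(run_type),
                    start=run_start,
                    end=run_end,
                    text=text[run_start:run_end],
                )
            )
        run_start, run_type = None, None

    for tok, tag in zip(sentence.tokens, tags):
        if tag.startswith("B-"):
            flush()
            run_start, run_end, run_type = tok.start, tok.end, tag[2:]
        elif tag.startswith("I-"):
            run_end = tok.end
        else:
            flush()
    flush()
    return entities


def to_conll(text: str, sentences: list[Sentence], entities: list[EntitySpan]) -> str:
    """CoNLL-style two-column export: token TAB tag, blank line per sentence."""
    blocks = []
    for sent in sentences:
        tags = encode_iob2(sent, entities)
        blocks.append(
            "\n".join(f"{tok.text}\t{tag}" for tok, tag in zip(sent.tokens, tags))
        )
    return "\n\n".join(blocks) + ("\n" if blocks else "")
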