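"""IOB2 encoding/decoding: format rules, repair, round-trips."""

import numpy as np
import pytest

from radstruct.corpus import Sentence
from radstruct.iob2 import (
    TAGS,
    Iob2Error,
    decode_iob2,
    encode_iob2,
    repair_tags,
    to_conll,
)
from radstruct.schema import EntitySpan, EntityType
from radstruct.text import regex_tokenize


def _sentence(text: str) -> Sentence:
    toks = regex_tokenize(text)
    return Sentence(start=0, end=len(text), tokens=toks)


def test_fifteen_tags():
    assert len(TAGS) == 15 and TAGS[0] == "O"


def test_no_entities_all_outside():
    sent = _sentence("no change seen")
    assert encode_iob2(sent, []) == ["O", "O", "O"]


def test_two_token_entity_gets_b_then_i():
    text = "pleural effusion seen"
    sent = _sentence(text)
    ent = EntitySpan("T1", EntityType.OBSERVATION, 0, 16, "pleural effusion")
    assert encode_iob2(sent, [ent]) == ["B-Observation", "I-Observation", "O"]


def test_overlapping_entities_cannot_encode():
    text = "right upper lobe"
    sent = _sentence(text)
    ents = [
        EntitySpan("T1", EntityType.ANATOMICAL_LOCATION, 0, 11, "right upper"),
        EntitySpan("T2", EntityType.ANATOMICAL_LOCATION, 6, 16, "upper lobe"),
    ]
    with pytest.raises(Iob2Error):
        encode_iob2(sent, ents)


def test_misaligned_token_is_split_at_entity_boundary():
    text = "30x14 mm"
    sent = _sentence(text)  # tokens: 30x14, mm
    ent = EntitySpan("T1", EntityType.SIZE, 3, 8, "14 mm")
    tags = encode_iob2(sent, [ent])
    assert [t.text for t in sent.tokens] == ["30x", "14", "mm"]
    assert tags == ["O", "B-Size", "I-Size"]


def test_decode_all_outside_gives_nothing():
    sent = _sentence("no change")
    assert decode_iob2("no change", sent, ["O", "O"]) == []


def test_decode_simple_run():
    text = "3 cm ."
    sent = _sentence(text)
    (ent,) = decode_iob2(text, sent, ["B-Size", "I-Size", "O"])
    assert (ent.type, ent.start, ent.end, ent.text) == (EntityType.SIZE, 0, 4, "3 cm")


def test_orphan_inside_tag_promoted_to_begin():
    assert repair_tags(["O", "I-Change"]) == ["O", "B-Change"]
    assert repair_tags(["B-Size", "I-Change"]) == ["B-Size", "B-Change"]
    text = "was reduced"
    sent = _sentence(text)
    (ent,) = decode_iob2(text, sent, ["O", "I-Change"])
    assert (ent.type, ent.text) == (EntityType.CHANGE, "reduced")


def test_length_mismatch_is_error():
    with pytest.raises(Iob2Error):
        decode_iob2("a b", _sentence("a b"), ["O"])


def test_round_trip_on_random_span_sets():
    """decode(encode(x)) = x for random non-overlapping token-aligned spans."""
    rng = np.random.default_rng(42)
    types = list(EntityType)
    for _ in range(1000):
        n_tokens = int(rng.integers(1, 15))
        words = [f"w{i}" for i in range(n_tokens)]
        text = " ".join(words)
        sent = _sentence(text)
        entities = []
        i = 0
        while i < n_tokens:
            if rng.random() < 0.4:
                span_len = int(rng.integers(1, min(3, n_tokens - i) + 1))
                start = sent.tokens[i].start
                end = sent.tokens[i + span_len - 1].end
                entities.append(
                    EntitySpan(
                        f"T{len(entities)}",
                        types[int(rng.integers(7))],
                        start, end, text[start:end],
                    )
                )
                i += span_len
            else:
                i += 1
        tags = encode_iob2(sent, entities)
        decoded = decode_iob2(text, sent, tags)
        assert [(e.type, e.start, e.end) for e in decoded] == [
            (e.type, e.start, e.end) for e in entities
        ]


def test_conll_export_shape(small_corpus):
    report = small_corpus[0]
    out = to_conll(report.text, report.sentences, report.entities)
    blocks = out.strip().split("\n\n")
    assert len(blocks) == len(report.sentences)
    first = blocks[0].splitlines()
    assert all("\t" in line for line in first)
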