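"""Relation extractor: candidates, marker encoding, classifier contracts."""

import pytest

from radstruct.corpus import AnnotatedReport, Sentence
from radstruct.relations import (
    MarkerVocabulary,
    RelHyperparams,
    RelModel,
    TruncationError,
    concatenate_report,
    dump_candidates,
    encode_candidate,
    expected_candidate_count,
    generate_candidates,
    predict_relations,
    score_candidates,
    train_rel,
)
from radstruct.schema import EntitySpan, EntityType, Relation, RelationType
from radstruct.text import regex_tokenize
from radstruct.vocab import Vocabulary


def _report(words: list[str], typed: dict[int, EntityType], rid="r") -> AnnotatedReport:
    """Build a one-sentence report; typed maps word index -> entity type."""
    text = " ".join(words)
    toks = regex_tokenize(text)
    sent = Sentence(0, len(text), tokens=toks)
    ents = []
    for i, etype in sorted(typed.items()):
        t = toks[i]
        ents.append(EntitySpan(f"T{len(ents)+1}", etype, t.start, t.end, t.text))
    return AnnotatedReport(id=rid, text=text, sentences=[sent], entities=ents)


def test_figure_counts_two_obs_three_modifiers():
    """2 observations x 3 modifiers and no findings -> 6 candidates."""
    report = _report(
        ["nodule", "mass", "large", "stable", "suspected"],
        {
            0: EntityType.OBSERVATION,
            1: EntityType.OBSERVATION,
            2: EntityType.CHARACTERISTICS,
            3: EntityType.CHANGE,
            4: EntityType.CERTAINTY,
        },
    )
    cands = generate_candidates(report)
    assert len(cands) == 6
    assert all(c.rel_type is RelationType.MODIFIER for c in cands)


def test_no_modifiers_no_findings_no_candidates():
    report = _report(
        ["nodule", "mass"],
        {0: EntityType.OBSERVATION, 1: EntityType.OBSERVATION},
    )
    assert generate_candidates(report) == []


def test_mixed_pairs_hand_enumeration():
    """2 OBS + 1 CF + 2 SIZE: modifier (2+1)x2 = 6, evidence 2x1 = 2."""
    report = _report(
        ["nodule", "mass", "cancer", "3", "5"],
        {
            0: EntityType.OBSERVATION,
            1: EntityType.OBSERVATION,
            2: EntityType.CLINICAL_FINDING,
            3: EntityType.SIZE,
            4: EntityType.SIZE,
        },
    )
    cands = generate_candidates(report)
    assert len(cands) == 8
    n_mod = sum(c.rel_type is RelationType.MODIFIER for c in cands)
    assert n_mod == 6 and len(cands) - n_mod == 2


def test_candidate_count_formula_on_corpus(small_corpus):
    for report in small_corpus:
        assert len(generate_candidates(report)) == expected_candidate_count(report)


def test_candidate_labels_follow_gold(small_corpus):
    for report in small_corpus[:5]:
        cands = generate_candidates(report)
        n_pos = sum(bool(c.label) for c in cands)
        assert n_pos == len(report.relations)


def test_concatenation_preserves_order_and_length(small_corpus):
    report = small_corpus[0]
    tokens = concatenate_report(report)
    assert len(tokens) == sum(len(s.tokens) for s in report.sentences)
    starts = [t.start for t in tokens]
    assert starts == sorted(starts)
    # every entity maps to a contiguous token run
    from radstruct.relations import entity_token_range

    for ent in report.entities:
        i, j = entity_token_range(tokens, ent)
        assert tokens[i].start == ent.start and tokens[j - 1].end == ent.end


def test_single_sentence_concatenation_is_identity():
    report = _report(["nodule", "seen"], {0: EntityType.OBSERVATION})
    assert concatenate_report(report) == report.sentences[0].tokens


def test_marker_encoding_paper_style_example():
    """'a 3 cm nodule is in the right upper lobe' gets exactly 4 markers."""
    words = "a 3 cm nodule is in the right upper lobe".split()
    text = " ".join(words)
    toks = regex_tokenize(text)
    sent = Sentence(0, len(text), tokens=toks)
    nod = EntitySpan("T1", EntityType.OBSERVATION, toks[3].start, toks[3].end, "nodule")
    loc = EntitySpan(
        "T2", EntityType.ANATOMICAL_LOCATION, toks[7].start, toks[9].end,
        "right upper lobe",
    )
    report = AnnotatedReport(id="r", text=text, sentences=[sent], entities=[nod, loc])
    (cand,) = generate_candidates(report)
    enc = encode_candidate(concatenate_report(report), cand, MarkerVocabulary(), 256)
    assert enc == [
        "a", "3", "cm", "<OBS>", "nodule", "</OBS>", "is", "in", "the",
        "<AE>", "right", "upper", "lobe", "</AE>",
    ]


def test_adjacent_entities_close_head_before_open_tail():
    report = _report(
        ["nodule", "cancer"],
        {0: EntityType.OBSERVATION, 1: EntityType.CLINICAL_FINDING},
    )
    (cand,) = generate_candidates(report)
    enc = encode_candidate(concatenate_report(report), cand, MarkerVocabulary(), 256)
    assert enc == ["<OBS>", "nodule", "</OBS>", "<CF>", "cancer", "</CF>"]


def test_marker_removal_recovers_contiguous_subsequence(small_corpus):
    mv = MarkerVocabulary()
    marker_set = set(mv.all_tokens())
    for report in small_corpus[:5]:
        tokens = concatenate_report(report)
        words = [t.text for t in tokens]
        for cand in generate_candidates(report)[:20]:
            enc = encode_candidate(tokens, cand, mv, 256)
            stripped = [w for w in enc if w not in marker_set]
            n = len(stripped)
            assert any(
                words[i : i + n] == stripped for i in range(len(words) - n + 1)
            )


def test_truncation_keeps_both_entities():
    words = (
        ["nodule"] + ["w"] * 100 + ["cancer"]
    )
    typed = {0: EntityType.OBSERVATION, 101: EntityType.CLINICAL_FINDING}
    report = _report(words, typed)
    (cand,) = generate_candidates(report)
    toks = concatenate_report(report)
    with pytest.raises(TruncationError):
        encode_candidate(toks, cand, MarkerVocabulary(), 48)
    enc = encode_candidate(toks, cand, MarkerVocabulary(), 110)
    assert len(enc) <= 110
    assert "<OBS>" in enc and "</OBS>" in enc
    assert "<CF>" in enc and "</CF>" in enc


def test_window_is_centered_between_entities():
    words = ["L"] * 30 + ["nodule"] + ["m"] * 8 + ["3"] + ["R"] * 30
    typed = {30: EntityType.OBSERVATION, 39: EntityType.SIZE}
    report = _report(words, typed)
    (cand,) = generate_candidates(report)
    enc = encode_candidate(concatenate_report(report), cand, MarkerVocabulary(), 20)
    assert len(enc) == 20
    assert enc.index("<OBS>") > 0 and enc.index("</SIZ>") < 19  # context both sides


def test_overlapping_candidate_pair_skipped():
    text = "pleural effusion"
    toks = regex_tokenize(text)
    sent = Sentence(0, len(text), tokens=toks)
    a = EntitySpan("T1", EntityType.OBSERVATION, 0, 16, "pleural effusion")
    b = EntitySpan("T2", EntityType.CHARACTERISTICS, 0, 7, "pleural")
    report = AnnotatedReport(id="r", text=text, sentences=[sent], entities=[a, b])
    cands = score_candidates(_untrained_model(), report)
    assert all(c.score is None for c in cands)  # skipped, never scored


def _untrained_model() -> RelModel:
    vocab = Vocabulary(["a", "nodule", "pleural", "effusion"])
    mv = MarkerVocabulary()
    for m in mv.all_tokens():
        vocab.add(m)
    return RelModel(
        vocab, RelHyperparams(embedding_dim=8, hidden_dim=8, seed=0), mv
    )


def test_no_entities_no_relations(small_corpus):
    model = _untrained_model()
    report = AnnotatedReport(id="r", text="nothing here .")
    assert predict_relations(model, report) == []


def test_threshold_monotonicity(small_corpus):
    """Raising the threshold never increases the number of relations."""
    model = _untrained_model()
    # give the model the corpus vocabulary so scores vary
    report = small_corpus[0]
    counts = []
    for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
        counts.append(len(predict_relations(model, report, threshold=thr)))
    assert counts == sorted(counts, reverse=True)


def test_predictions_subset_of_candidates_and_schema_valid(small_corpus):
    model = _untrained_model()
    report = small_corpus[1]
    cands = {
        (c.rel_type, id(c.head), id(c.tail)) for c in generate_candidates(report)
    }
    for rel in predict_relations(model, report, threshold=0.0):
        rel.validate()
        assert (rel.type, id(rel.head), id(rel.tail)) in cands


def test_all_positive_training_is_degenerate_sanity():
    """If every candidate is positive the model predicts positive everywhere."""
    reports = []
    for i in range(8):
        r = _report(
            ["nodule", "stable"],
            {0: EntityType.OBSERVATION, 1: EntityType.CHANGE},
            rid=f"r{i}",
        )
        r.relations = [
            Relation("R1", RelationType.MODIFIER, r.entities[0], r.entities[1])
        ]
        reports.append(r)
    hp = RelHyperparams(
        embedding_dim=12, hidden_dim=12, batch_size=4, max_epochs=5, seed=1
    )
    model, _ = train_rel(reports[:6], reports[6:], hp)
    for r in reports[6:]:
        assert len(predict_relations(model, r)) == 1


def test_training_without_positives_rejected():
    r = _report(
        ["nodule", "stable"],
        {0: EntityType.OBSERVATION, 1: EntityType.CHANGE},
    )
    r.relations = []
    # label attachment requires gold; force empty-positive training set
    with pytest.raises(ValueError):
        train_rel([r], [], RelHyperparams(max_epochs=1))


def test_class_imbalance_negatives_dominate(small_corpus):
    n_pos = n_neg = 0
    for report in small_corpus:
        for cand in generate_candidates(report):
            if cand.label:
                n_pos += 1
            else:
                n_neg += 1
    assert n_neg >= n_pos > 0


def test_candidate_dump_format(small_corpus):
    cands = generate_candidates(small_corpus[0])
    dump = dump_candidates(cands)
    lines = dump.strip().splitlines()
    assert lines[0].split("\t") == [
        "report_id", "rel_type", "head_id", "tail_id", "label", "score",
    ]
    assert len(lines) == len(cands) + 1


def test_rel_checkpoint_round_trip(tmp_path):
    reports = []
    for i in range(4):
        r = _report(
            ["nodule", "stable"],
            {0: EntityType.OBSERVATION, 1: EntityType.CHANGE},
            rid=f"r{i}",
        )
        r.relations = [
            Relation("R1", RelationType.MODIFIER, r.entities[0], r.entities[1])
        ]
        reports.append(r)
    hp = RelHyperparams(
        embedding_dim=12, hidden_dim=12, batch_size=4, max_epochs=2, seed=1
    )
    model, _ = train_rel(reports, [], hp)
    path = tmp_path / "rel.ckpt"
    model.save(path)
    loaded = RelModel.load(path)
    orig = [c.score for c in score_candidates(model, reports[0])]
    back = [c.score for c in score_candidates(loaded, reports[0])]
    assert orig == pytest.approx(back)
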