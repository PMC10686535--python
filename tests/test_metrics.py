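"""Evaluation metrics: strict F1, coverage, kappa, major/minor analysis."""

import pytest
from sklearn.metrics import cohen_kappa_score

from radstruct.metrics import (
    CoverageCounts,
    UndefinedMetricError,
    cohen_kappa,
    coverage,
    entity_f1,
    major_minor_f1,
    major_minor_split,
    relation_f1,
)
from radstruct.schema import EntitySpan, EntityType, Relation, RelationType
from radstruct.synthetic import STOPWORDS


def _ent(tid, etype, start, end):
    return EntitySpan(tid, etype, start, end, "x" * (end - start))


def test_identical_predictions_score_100():
    gold = [_ent("T1", EntityType.OBSERVATION, 0, 5),
            _ent("T2", EntityType.SIZE, 6, 8)]
    m = entity_f1(gold, list(gold))
    assert m.micro.f1 == 1.0 and m.micro.tp == 2


def test_empty_predictions_score_0():
    gold = [_ent("T1", EntityType.OBSERVATION, 0, 5)]
    m = entity_f1(gold, [])
    assert m.micro.f1 == 0.0 and m.micro.fn == 1


def test_hand_counted_mixed_case():
    """gold {A,B,C}, predicted {A, B-with-wrong-end, D}: P = R = F1 = 1/3."""
    A = _ent("T1", EntityType.OBSERVATION, 0, 5)
    B = _ent("T2", EntityType.SIZE, 6, 10)
    C = _ent("T3", EntityType.CHANGE, 12, 20)
    B_bad = _ent("P2", EntityType.SIZE, 6, 11)
    D = _ent("P3", EntityType.CERTAINTY, 30, 35)
    m = entity_f1([A, B, C], [A, B_bad, D])
    assert (m.micro.tp, m.micro.fp, m.micro.fn) == (1, 2, 2)
    assert m.micro.precision == pytest.approx(1 / 3)
    assert m.micro.f1 == pytest.approx(1 / 3)


def test_micro_equals_pooled_counts_random_fixtures(rng):
    """Micro-F1 from class pooling matches a brute-force set computation."""
    types = list(EntityType)
    for _ in range(100):
        gold, pred = [], []
        for i in range(int(rng.integers(0, 15))):
            s = int(rng.integers(0, 40))
            gold.append(_ent(f"T{i}", types[int(rng.integers(7))], s, s + 2))
        for i in range(int(rng.integers(0, 15))):
            s = int(rng.integers(0, 40))
            pred.append(_ent(f"P{i}", types[int(rng.integers(7))], s, s + 2))
        m = entity_f1(gold, pred).micro
        # independent oracle: greedy multiset intersection on exact keys
        from collections import Counter

        gk = Counter((e.type, e.start, e.end) for e in gold)
        pk = Counter((e.type, e.start, e.end) for e in pred)
        tp = sum((gk & pk).values())
        fp = len(pred) - tp
        fn = len(gold) - tp
        assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        assert m.f1 == pytest.approx(f)


def test_relation_f1_gold_mode_identity():
    obs = _ent("T1", EntityType.OBSERVATION, 0, 5)
    size = _ent("T2", EntityType.SIZE, 6, 8)
    rel = Relation("R1", RelationType.MODIFIER, obs, size)
    m = relation_f1([rel], [rel], mode="gold_entities")
    assert m.micro.f1 == 1.0
    assert "Modifier:Size" in m.per_class


def test_relation_endpoint_boundary_error_costs_fp_and_fn():
    obs = _ent("T1", EntityType.OBSERVATION, 0, 5)
    size = _ent("T2", EntityType.SIZE, 6, 8)
    cf = _ent("T3", EntityType.CLINICAL_FINDING, 10, 16)
    gold = [
        Relation("R1", RelationType.MODIFIER, obs, size),
        Relation("R2", RelationType.EVIDENCE, obs, cf),
    ]
    obs_bad = _ent("P1", EntityType.OBSERVATION, 0, 4)
    pred = [
        Relation("R1", RelationType.MODIFIER, obs_bad, size),
        Relation("R2", RelationType.EVIDENCE, obs, cf),
    ]
    m = relation_f1(gold, pred, mode="pipeline")
    assert (m.micro.tp, m.micro.fp, m.micro.fn) == (1, 1, 1)


def test_coverage_arithmetic_entire_sequence():
    counts = CoverageCounts(b_tagged=7050, i_tagged=0, o_tagged=10036 - 7050)
    assert counts.percentage == pytest.approx(70.2, abs=0.05)


def test_coverage_arithmetic_filtered():
    counts = CoverageCounts(b_tagged=6595, i_tagged=0, o_tagged=6853 - 6595)
    assert counts.percentage == pytest.approx(96.2, abs=0.05)


def test_coverage_undefined_without_tokens():
    with pytest.raises(UndefinedMetricError):
        CoverageCounts().percentage


def test_coverage_fully_annotated_is_100(small_corpus):
    report = small_corpus[0]
    # keep only sentences whose every token is inside an entity: synthetic
    # reports have none, so instead check the invariant on the filtered side
    result = coverage([report], STOPWORDS)
    assert result.filtered.percentage >= result.entire.percentage


def test_coverage_excludes_flagged_sentences(small_corpus):
    result = coverage(small_corpus, STOPWORDS)
    n_flagged = sum(
        s.out_of_scope for r in small_corpus for s in r.sentences
    )
    assert result.entire.excluded_sentences == n_flagged
    total_tokens = sum(
        len(s.tokens)
        for r in small_corpus
        for s in r.sentences
        if not s.out_of_scope
    )
    assert result.entire.total == total_tokens
    assert result.filtered.total + result.filtered.excluded_tokens == total_tokens


def test_kappa_perfect_agreement():
    assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)


def test_kappa_hand_computed_2x2_table():
    """TP=40, FN=10, FP=10, TN=40: p_o = 0.8, p_e = 0.5, kappa = 0.6."""
    a = [1] * 50 + [0] * 50
    b = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
    assert cohen_kappa(a, b) == pytest.approx(0.6)


def test_kappa_independent_labels_near_zero(rng):
    a = rng.integers(0, 2, size=20000)
    b = rng.integers(0, 2, size=20000)
    assert abs(cohen_kappa(list(a), list(b))) < 0.05


def test_kappa_degenerate_marginals_undefined():
    with pytest.raises(UndefinedMetricError):
        cohen_kappa([1, 1, 1], [1, 1, 1])


def test_kappa_matches_sklearn(rng):
    for _ in range(20):
        n = int(rng.integers(10, 60))
        a = list(rng.integers(0, 2, size=n))
        b = list(rng.integers(0, 2, size=n))
        if len(set(a)) == 1 and len(set(b)) == 1 and a[0] == b[0]:
            continue
        assert cohen_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )


def test_major_minor_assignment_rule():
    def report_with(texts, rid):
        from radstruct.corpus import AnnotatedReport

        text = " ".join(texts)
        ents, pos = [], 0
        for i, t in enumerate(texts):
            ents.append(
                EntitySpan(f"T{i}", EntityType.OBSERVATION, pos, pos + len(t), t)
            )
            pos += len(t) + 1
        return AnnotatedReport(id=rid, text=text, entities=ents)

    train = [report_with(["nodule"] * 5 + ["cyst"], "tr")]
    test = [report_with(["nodule", "cyst", "mass"], "te")]
    major, minor = major_minor_split(train, test)
    assert [e.text for e in major[0]] == ["nodule"]  # seen 5x -> major
    assert [e.text for e in minor[0]] == ["cyst", "mass"]  # 1x / unseen


def test_major_minor_partition_property(small_corpus):
    train, test = small_corpus[:20], small_corpus[20:]
    major, minor = major_minor_split(train, test)
    for r, mj, mn in zip(test, major, minor):
        assert len(mj) + len(mn) == len(r.entities)
        assert not ({id(e) for e in mj} & {id(e) for e in mn})


def test_major_minor_f1_with_perfect_predictions(small_corpus):
    train, test = small_corpus[:20], small_corpus[20:]
    preds = [list(r.entities) for r in test]
    mj, mn = major_minor_f1(train, test, preds)
    assert mj.micro.f1 == 1.0 and mn.micro.f1 == 1.0
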