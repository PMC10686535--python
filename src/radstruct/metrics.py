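"""Evaluation metrics: entity/relation F1, coverage, Cohen kappa, major/minor.

Entity matching is strict: a predicted span counts as a true positive
only if an unmatched gold entity has the identical (type, start, end).
A predicted relation matches only if its type and both endpoint spans
match exactly and the gold pair is related.  Per-class scores are pooled
by microaveraging (summing TP/FP/FN before computing P/R/F1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd

from .corpus import AnnotatedReport
from .iob2 import encode_iob2
from .schema import EntitySpan, Relation, RelationType
from .text import is_punctuation


class UndefinedMetricError(ArithmeticError):
    """The metric has no defined value for this input (not zero)."""


@dataclass
class ClassMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)

    @property
    def micro(self) -> ClassMetrics:
        return ClassMetrics(
            tp=sum(c.tp for c in self.per_class.values()),
            fp=sum(c.fp for c in self.per_class.values()),
            fn=sum(c.fn for c in self.per_class.values()),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in sorted(self.per_class):
            c = self.per_class[label]
            rows.append(
                {
                    "class": label, "tp": c.tp, "fp": c.fp, "fn": c.fn,
                    "precision": c.precision, "recall": c.recall, "f1": c.f1,
                }
            )
        m = self.micro
        rows.append(
            {
                "class": "microaverage", "tp": m.tp, "fp": m.fp, "fn": m.fn,
                "precision": m.precision, "recall": m.recall, "f1": m.f1,
            }
        )
        return pd.DataFrame(rows)


def _pair_report_lists(gold: Sequence, predicted: Sequence) -> tuple[list, list]:
    """Accept flat lists (one report) or parallel lists of per-report lists."""

    def nested(items):
        return bool(items) and isinstance(items[0], (list, tuple))

    if nested(gold) or nested(predicted):
        gold_lists = [list(x) for x in gold]
        pred_lists = [list(x) for x in predicted]
    else:  # both flat: a single report's annotations
        gold_lists, pred_lists = [list(gold)], [list(predicted)]
    if len(gold_lists) != len(pred_lists):
        raise ValueError("gold and predicted must cover the same report set")
    return gold_lists, pred_lists


def _entity_key(e: EntitySpan) -> tuple:
    return (e.type, e.start, e.end)


def entity_f1(gold, predicted) -> MetricsReport:
    """Strict entity-level F1 with one-to-one (type, start, end) matching.

    ``gold`` and ``predicted`` are parallel per-report lists of
    :class:`EntitySpan` (or single flat lists for one report).
    """
    gold_lists, pred_lists = _pair_report_lists(gold, predicted)
    report = MetricsReport()
    for g_list, p_list in zip(gold_lists, pred_lists):
        g_keys = Counter(_entity_key(e) for e in g_list)
        for e in p_list:
            cls = report.per_class.setdefault(e.type.brat_label, ClassMetrics())
            key = _entity_key(e)
            if g_keys[key] > 0:
                g_keys[key] -= 1
                cls.tp += 1
            else:
                cls.fp += 1
        for key, n in g_keys.items():
            cls = report.per_class.setdefault(key[0].brat_label, ClassMetrics())
            cls.fn += n
    return report


def _relation_class(rel: Relation) -> str:
    if rel.type is RelationType.MODIFIER:
        return f"Modifier:{rel.tail.type.brat_label}"
    return "Evidence:Clinical_finding"


def _relation_key(rel: Relation) -> tuple:
    return (rel.type, _entity_key(rel.head), _entity_key(rel.tail))


def relation_f1(gold, predicted, mode: str = "gold_entities") -> MetricsReport:
    """Relation F1; a TP needs exact type + both endpoint spans + the link.

    ``mode`` records whether predictions reference gold entities
    ("gold_entities") or entities produced by the tagger ("pipeline");
    the matching rule is identical — in pipeline mode an entity boundary
    error automatically turns its relations into FP/FN pairs.  Modifier
    relations are reported per tail entity type.
    """
    if mode not in ("gold_entities", "pipeline"):
        raise ValueError(f"unknown mode {mode!r}")
    gold_lists, pred_lists = _pair_report_lists(gold, predicted)
    report = MetricsReport()
    for g_list, p_list in zip(gold_lists, pred_lists):
        g_keys = Counter(_relation_key(r) for r in g_list)
        for r in p_list:
            cls = report.per_class.setdefault(_relation_class(r), ClassMetrics())
            key = _relation_key(r)
            if g_keys[key] > 0:
                g_keys[key] -= 1
                cls.tp += 1
            else:
                cls.fp += 1
        for key, n in g_keys.items():
            label = (
                f"Modifier:{key[2][0].brat_label}"
                if key[0] is RelationType.MODIFIER
                else "Evidence:Clinical_finding"
            )
            cls = report.per_class.setdefault(label, ClassMetrics())
            cls.fn += n
    return report


# ---------------------------------------------------------------------------
# Coverage


@dataclass
class CoverageCounts:
    b_tagged: int = 0
    i_tagged: int = 0
    o_tagged: int = 0
    excluded_sentences: int = 0
    excluded_tokens: int = 0

    @property
    def annotated(self) -> int:
        return self.b_tagged + self.i_tagged

    @property
    def total(self) -> int:
        return self.b_tagged + self.i_tagged + self.o_tagged

    @property
    def percentage(self) -> float:
        """Coverage(%) = (B + I) / (B + I + O) x 100."""
        if self.total == 0:
            raise UndefinedMetricError("coverage undefined: no eligible tokens")
        return 100.0 * self.annotated / self.total


@dataclass
class CoverageResult:
    entire: CoverageCounts
    filtered: CoverageCounts


def coverage(
    corpus: Iterable[AnnotatedReport],
    stop_words: Iterable[str] = (),
    excluder: Callable[[str], bool] | None = None,
) -> CoverageResult:
    """Fraction of tokens inside annotated entity spans.

    Sentences judged out of the information-model scope (technique /
    procedure / recommendation text) contribute nothing: they are
    excluded either by the sentence's gold ``out_of_scope`` flag or by
    the supplied ``excluder`` predicate on the sentence text.  The
    ``filtered`` variant additionally removes punctuation tokens and
    tokens from the ``stop_words`` list from all three counts.
    """
    stop = {w.lower() for w in stop_words}
    entire = CoverageCounts()
    filtered = CoverageCounts()
    for report in corpus:
        for sent in report.sentences:
            excluded = sent.out_of_scope
            if excluder is not None:
                excluded = excluded or excluder(report.text[sent.start : sent.end])
            if excluded:
                entire.excluded_sentences += 1
                filtered.excluded_sentences += 1
                continue
            tags = encode_iob2(sent, report.entities, split_misaligned=False)
            for tok, tag in zip(sent.tokens, tags):
                slot = "b_tagged" if tag.startswith("B") else (
                    "i_tagged" if tag.startswith("I") else "o_tagged"
                )
                setattr(entire, slot, getattr(entire, slot) + 1)
                if is_punctuation(tok.text) or tok.text.lower() in stop:
                    filtered.excluded_tokens += 1
                else:
                    setattr(filtered, slot, getattr(filtered, slot) + 1)
    return CoverageResult(entire=entire, filtered=filtered)


# ---------------------------------------------------------------------------
# Agreement


def cohen_kappa(annotator_a: Sequence, annotator_b: Sequence) -> float:
    """Cohen kappa = (p_o - p_e) / (1 - p_e) over two parallel labelings."""
    if len(annotator_a) != len(annotator_b):
        raise ValueError("annotators must label the same candidate set")
    n = len(annotator_a)
    if n == 0:
        raise UndefinedMetricError("kappa undefined for empty labelings")
    p_o = sum(a == b for a, b in zip(annotator_a, annotator_b)) / n
    labels = set(annotator_a) | set(annotator_b)
    ca = Counter(annotator_a)
    cb = Counter(annotator_b)
    p_e = sum((ca[l] / n) * (cb[l] / n) for l in labels)
    if p_e >= 1.0:
        raise UndefinedMetricError("kappa undefined: degenerate marginals (p_e = 1)")
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Major/minor mention analysis


def mention_frequencies(corpus: Iterable[AnnotatedReport]) -> Counter:
    """Surface-string frequency of entity mentions over a corpus."""
    return Counter(e.text for r in corpus for e in r.entities)


def major_minor_split(
    train_corpus: Sequence[AnnotatedReport],
    test_corpus: Sequence[AnnotatedReport],
) -> tuple[list[list[EntitySpan]], list[list[EntitySpan]]]:
    """Partition test gold entities by training-mention frequency.

    A mention string occurring >= 2 times in the training annotations is
    "major"; occurring once or never is "minor".  Returns per-report
    (major, minor) lists that partition the test entities.
    """
    freq = mention_frequencies(train_corpus)
    major, minor = [], []
    for report in test_corpus:
        major.append([e for e in report.entities if freq[e.text] >= 2])
        minor.append([e for e in report.entities if freq[e.text] < 2])
    return major, minor


def major_minor_f1(
    train_corpus: Sequence[AnnotatedReport],
    test_corpus: Sequence[AnnotatedReport],
    predictions: Sequence[list[EntitySpan]],
) -> tuple[MetricsReport, MetricsReport]:
    """Entity F1 on the major and minor test subsets.

    Predictions are assigned to a subset by the same training-frequency
    rule applied to their own surface strings, so each subset's score
    pairs its gold entities with the predictions of like frequency.
    """
    freq = mention_frequencies(train_corpus)
    gold_major, gold_minor = major_minor_split(train_corpus, test_corpus)
    pred_major = [[e for e in p if freq[e.text] >= 2] for p in predictions]
    pred_minor = [[e for e in p if freq[e.text] < 2] for p in predictions]
    return (
        entity_f1(gold_major, pred_major),
        entity_f1(gold_minor, pred_minor),
    )
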