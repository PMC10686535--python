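"""Synthetic annotated radiology-style report generator.

Real CT-report corpora with gold entity/relation annotations are rarely
redistributable, so this module generates structurally realistic stand-in
corpora with known gold annotations: multi-sentence reports (about 12
sentences on average), entities drawn from the 7-type information model
with a long-tailed (Zipf) mention vocabulary, modifier relations within a
sentence, evidence relations that cross sentence boundaries with a
configurable probability, and a fraction of out-of-scope sentences
(imaging technique / procedure / recommendation text) carrying no
annotations.  Linguistic realism is explicitly not a goal — the corpus is
a pseudo-clinical controlled language — but the annotation *topology* that
the extraction pipeline and the evaluation metrics depend on is faithful.

Reports also contain unrelated observation-finding pairs in the same
report, so relation classification cannot be solved by entity-type
constraints alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus import AnnotatedReport, Sentence, Token
from .schema import (
    EntitySpan,
    EntityType,
    Relation,
    RelationType,
)


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Controlled vocabulary.  Lists are ordered by intended frequency rank; a
# Zipf distribution over ranks yields the major/minor mention split.

DEFAULT_VOCAB: dict[EntityType, list[str]] = {
    EntityType.OBSERVATION: [
        "nodule", "mass", "pleural effusion", "ground glass opacity", "cyst",
        "calcification", "lymphadenopathy", "consolidation", "low density area",
        "atelectasis", "emphysema", "wall thickening", "fatty liver",
        "gallstone", "ascites", "stenosis", "dilatation", "air trapping",
        "granuloma", "infiltrate", "honeycombing", "bronchiectasis",
        "fibrosis", "hematoma", "aneurysm", "mucous plug", "nodular shadow",
        "fluid collection", "pneumothorax", "pericardial effusion",
    ],
    EntityType.CLINICAL_FINDING: [
        "lung cancer", "metastasis", "pneumonia", "tuberculosis", "lymphoma",
        "hepatocellular carcinoma", "pancreatitis", "cholecystitis", "ileus",
        "abscess", "cirrhosis", "sarcoidosis", "interstitial pneumonia",
        "malignancy", "recurrence", "biloma", "empyema", "diverticulitis",
    ],
    EntityType.ANATOMICAL_LOCATION: [
        "right upper lobe", "left lower lobe", "liver", "right lower lobe",
        "pancreas", "left upper lobe", "spleen", "right kidney", "left kidney",
        "gallbladder", "middle lobe", "mediastinum", "pancreatic duct",
        "bile duct", "portal vein", "stomach", "colon", "small bowel",
        "pelvis", "adrenal gland", "pleura", "bronchus", "aorta",
        "hepatic segment four", "paraaortic region",
    ],
    EntityType.CERTAINTY: [
        "suspected", "possible", "definite", "probable", "likely",
        "equivocal", "unlikely", "known", "questionable", "presumed",
    ],
    EntityType.CHANGE: [
        "unchanged", "increased", "decreased", "new", "enlarged",
        "resolved", "reduced", "stable", "progressed", "improved",
    ],
    EntityType.CHARACTERISTICS: [
        "solid", "cystic", "calcified", "ill defined", "well defined",
        "multiple", "diffuse", "hypodense", "ring enhancing", "irregular",
        "hyperdense", "smooth", "lobulated", "spiculated", "tiny",
    ],
    EntityType.SIZE: (
        [f"{n} mm" for n in (12, 5, 8, 3, 20, 15, 10, 25, 6, 30, 18, 4, 35, 40, 22, 45)]
        + [f"{n} cm" for n in (3, 1, 2, 5, 4, 6, 8, 10)]
        + [
            "30 x 14 mm", "12 x 8 mm", "25 x 10 mm", "40 x 22 mm",
            "15 x 9 mm", "22 x 18 mm", "10 x 6 mm", "35 x 20 mm",
        ]
    ),
}

#: Filler tokens carrying no clinical content (the stop-word list used by
#: the coverage metric).
STOPWORDS: list[str] = [
    "a", "the", "is", "are", "in", "of", "with", "there", "seen",
    "noted", "and", "these", "findings", "suggest", "suggesting",
    "measuring", "this", "for", "on", "at",
]

#: Non-stop filler phrases (content-like O tokens kept in the filtered
#: coverage denominator).
_TRAILERS = [
    ["on", "current", "study"],
    ["since", "prior", "examination"],
    ["at", "this", "time"],
]

_OUT_OF_SCOPE_TEMPLATES = [
    "technique : contrast enhanced ct of the trunk",
    "technique : plain ct scan",
    "procedure : status post surgical resection",
    "recommend followup imaging in three months",
    "recommend clinical correlation",
    "comparison : prior ct examination available",
]

#: First tokens identifying out-of-scope sentences (the default exclusion
#: pattern list for the coverage metric on this corpus).
OUT_OF_SCOPE_MARKERS = ("technique", "procedure", "recommend", "comparison")


def default_scope_excluder(sentence_text: str) -> bool:
    """True if a sentence is out of the information-model scope."""
    first = sentence_text.split(maxsplit=1)
    return bool(first) and first[0].lower() in OUT_OF_SCOPE_MARKERS


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    Defaults emulate the structure of an annotated CT-report corpus:
    about 12 sentences per report with 8.4% out-of-scope sentences, a
    long-tailed mention vocabulary (Zipf exponent 1.1) and a fifth of
    evidence relations crossing sentence boundaries.
    """

    n_reports: int = 100
    sentences_per_report: float = 12.0
    vocab: dict[EntityType, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_VOCAB.items()}
    )
    zipf_exponent: float = 1.1
    p_cross_sentence_evidence: float = 0.2
    p_out_of_scope_sentence: float = 0.084
    p_finding_sentence: float = 0.25
    stopword_rate: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        for p in (
            self.p_cross_sentence_evidence,
            self.p_out_of_scope_sentence,
            self.p_finding_sentence,
            self.stopword_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0,1]")
        if self.n_reports < 0:
            raise ConfigError("n_reports must be nonnegative")
        for etype in EntityType:
            if not self.vocab.get(etype):
                raise ConfigError(f"empty mention vocabulary for {etype.name}")

    def echo(self) -> dict:
        d = asdict(self)
        d["vocab"] = {t.name: v for t, v in self.vocab.items()}
        return d


class _ZipfSampler:
    def __init__(self, items: list[str], exponent: float):
        self.items = items
        ranks = np.arange(1, len(items) + 1, dtype=float)
        w = ranks ** (-exponent)
        self.probs = w / w.sum()

    def sample(self, rng: np.random.Generator) -> str:
        return self.items[int(rng.choice(len(self.items), p=self.probs))]


# Modifier types realized before the concept mention vs after it.
_PRE_MODIFIERS = [EntityType.CERTAINTY, EntityType.CHANGE, EntityType.CHARACTERISTICS]
_POST_MODIFIERS = [EntityType.SIZE, EntityType.ANATOMICAL_LOCATION]
_N_MODIFIER_PROBS = np.array([0.20, 0.40, 0.25, 0.10, 0.05])  # 0..4 modifiers


class _ReportBuilder:
    """Accumulates tokens/entities/relations for one report."""

    def __init__(self, report_id: str):
        self.id = report_id
        self.pieces: list[str] = []
        self.cursor = 0
        self.sentences: list[Sentence] = []
        self.entities: list[EntitySpan] = []
        self.relations: list[Relation] = []
        self._sent_tokens: list[Token] = []
        self._sent_start: int | None = None

    def add_token(self, word: str) -> Token:
        if self.pieces:
            self.pieces.append(" ")
            self.cursor += 1
        if self._sent_start is None:
            self._sent_start = self.cursor
        tok = Token(self.cursor, self.cursor + len(word), word)
        self.pieces.append(word)
        self.cursor += len(word)
        self._sent_tokens.append(tok)
        return tok

    def add_mention(self, etype: EntityType, mention: str) -> EntitySpan:
        words = mention.split(" ")
        first = self.add_token(words[0])
        last = first
        for w in words[1:]:
            last = self.add_token(w)
        ent = EntitySpan(
            id=f"T{len(self.entities) + 1}",
            type=etype,
            start=first.start,
            end=last.end,
            text=mention,
        )
        self.entities.append(ent)
        return ent

    def add_relation(
        self, rtype: RelationType, head: EntitySpan, tail: EntitySpan
    ) -> None:
        self.relations.append(
            Relation(id=f"R{len(self.relations) + 1}", type=rtype, head=head, tail=tail)
        )

    def end_sentence(self, out_of_scope: bool = False) -> None:
        self.add_token(".")
        self.sentences.append(
            Sentence(
                start=self._sent_start,
                end=self.cursor,
                tokens=self._sent_tokens,
                out_of_scope=out_of_scope,
            )
        )
        self._sent_tokens = []
        self._sent_start = None

    def build(self, source: str) -> AnnotatedReport:
        report = AnnotatedReport(
            id=self.id,
            text="".join(self.pieces),
            sentences=self.sentences,
            entities=self.entities,
            relations=self.relations,
            source=source,
        )
        report.validate()
        return report


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedReport]:
    """Generate ``config.n_reports`` annotated reports (seed-deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samplers = {
        t: _ZipfSampler(config.vocab[t], config.zipf_exponent) for t in EntityType
    }
    reports = []
    for i in range(config.n_reports):
        source = "chest" if i % 2 == 0 else "abdomen"
        reports.append(_generate_report(f"r{i:04d}", source, config, samplers, rng))
    return reports


def _generate_report(
    report_id: str,
    source: str,
    config: GeneratorConfig,
    samplers: dict[EntityType, _ZipfSampler],
    rng: np.random.Generator,
) -> AnnotatedReport:
    n_sentences = max(3, int(rng.poisson(config.sentences_per_report)))
    builder = _ReportBuilder(report_id)
    observations: list[EntitySpan] = []
    for _ in range(n_sentences):
        u = rng.random()
        if u < config.p_out_of_scope_sentence:
            template = _OUT_OF_SCOPE_TEMPLATES[
                int(rng.integers(len(_OUT_OF_SCOPE_TEMPLATES)))
            ]
            for w in template.split(" "):
                builder.add_token(w)
            builder.end_sentence(out_of_scope=True)
        elif u < config.p_out_of_scope_sentence + config.p_finding_sentence:
            _finding_sentence(builder, observations, config, samplers, rng)
        else:
            obs = _observation_sentence(builder, config, samplers, rng)
            observations.append(obs)
    return builder.build(source)


def _sample_modifier_types(rng: np.random.Generator) -> list[EntityType]:
    k = int(rng.choice(5, p=_N_MODIFIER_PROBS))
    all_mods = _PRE_MODIFIERS + _POST_MODIFIERS
    idx = rng.choice(len(all_mods), size=k, replace=False)
    return [all_mods[j] for j in sorted(idx)]


def _maybe(rng: np.random.Generator, p: float) -> bool:
    return rng.random() < p


def _concept_with_modifiers(
    builder: _ReportBuilder,
    concept_type: EntityType,
    config: GeneratorConfig,
    samplers: dict[EntityType, _ZipfSampler],
    rng: np.random.Generator,
) -> EntitySpan:
    """Emit '<pre-mods> <concept> [measuring <size>] [in the <loc>]'."""
    mod_types = _sample_modifier_types(rng)
    pre = [t for t in mod_types if t in _PRE_MODIFIERS]
    post = [t for t in mod_types if t in _POST_MODIFIERS]
    pre_entities = [(t, builder.add_mention(t, samplers[t].sample(rng))) for t in pre]
    concept = builder.add_mention(concept_type, samplers[concept_type].sample(rng))
    for t, ent in pre_entities:
        builder.add_relation(RelationType.MODIFIER, concept, ent)
    for t in post:
        if t is EntityType.SIZE:
            builder.add_token("measuring")
        else:
            if _maybe(rng, config.stopword_rate):
                builder.add_token("seen")
            builder.add_token("in")
            builder.add_token("the")
        ent = builder.add_mention(t, samplers[t].sample(rng))
        builder.add_relation(RelationType.MODIFIER, concept, ent)
    return concept


def _observation_sentence(
    builder, config, samplers, rng
) -> EntitySpan:
    if _maybe(rng, config.stopword_rate):
        builder.add_token("there")
        builder.add_token("is")
    builder.add_token("a")
    obs = _concept_with_modifiers(
        builder, EntityType.OBSERVATION, config, samplers, rng
    )
    if _maybe(rng, 0.15):
        for w in _TRAILERS[int(rng.integers(len(_TRAILERS)))]:
            builder.add_token(w)
    builder.end_sentence()
    return obs


def _finding_sentence(
    builder,
    observations: list[EntitySpan],
    config,
    samplers,
    rng,
) -> None:
    cross = observations and _maybe(rng, config.p_cross_sentence_evidence)
    if cross:
        # Evidence observation lies in an earlier sentence.
        builder.add_token("these")
        builder.add_token("findings")
        builder.add_token("suggest")
        finding = _concept_with_modifiers(
            builder, EntityType.CLINICAL_FINDING, config, samplers, rng
        )
        builder.add_relation(RelationType.EVIDENCE, observations[-1], finding)
    else:
        builder.add_token("a")
        obs = _concept_with_modifiers(
            builder, EntityType.OBSERVATION, config, samplers, rng
        )
        builder.add_token("suggesting")
        finding = _concept_with_modifiers(
            builder, EntityType.CLINICAL_FINDING, config, samplers, rng
        )
        builder.add_relation(RelationType.EVIDENCE, obs, finding)
        observations.append(obs)
    builder.end_sentence()


# ---------------------------------------------------------------------------
# Corpus summaries


@dataclass
class CorpusStatistics:
    n_reports: int
    n_sentences: int
    n_out_of_scope_sentences: int
    entity_counts: dict[str, int]
    relation_counts: dict[str, int]
    mention_frequencies: Counter
    n_evidence: int
    n_cross_sentence_evidence: int

    @property
    def total_entities(self) -> int:
        return sum(self.entity_counts.values())

    @property
    def total_relations(self) -> int:
        return sum(self.relation_counts.values())

    @property
    def cross_sentence_evidence_fraction(self) -> float:
        return (
            self.n_cross_sentence_evidence / self.n_evidence
            if self.n_evidence
            else 0.0
        )


def corpus_statistics(corpus: list[AnnotatedReport]) -> CorpusStatistics:
    """Exact entity/relation counts and the mention-frequency histogram."""
    entity_counts = {t.name: 0 for t in EntityType}
    relation_counts = {r.name: 0 for r in RelationType}
    mentions: Counter = Counter()
    n_sent = n_oos = n_ev = n_cross = 0
    for report in corpus:
        n_sent += len(report.sentences)
        n_oos += sum(1 for s in report.sentences if s.out_of_scope)
        for ent in report.entities:
            entity_counts[ent.type.name] += 1
            mentions[(ent.type.name, ent.text)] += 1
        for rel in report.relations:
            relation_counts[rel.type.name] += 1
            if rel.type is RelationType.EVIDENCE:
                n_ev += 1
                if report.sentence_index_of(rel.head) != report.sentence_index_of(
                    rel.tail
                ):
                    n_cross += 1
    return CorpusStatistics(
        n_reports=len(corpus),
        n_sentences=n_sent,
        n_out_of_scope_sentences=n_oos,
        entity_counts=entity_counts,
        relation_counts=relation_counts,
        mention_frequencies=mentions,
        n_evidence=n_ev,
        n_cross_sentence_evidence=n_cross,
    )
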