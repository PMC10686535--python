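"""End-to-end orchestration: splitting, the 2-stage pipeline, experiments.

The 2-stage system runs entity extraction first and feeds the extracted
entities into relation extraction; its output is a schema-valid
annotated report serializable to BRAT standoff or to line-delimited
structured records (one record per concept entity with its attached
modifiers and evidence links).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .brat import prepare_report
from .corpus import AnnotatedReport
from .metrics import MetricsReport, entity_f1, relation_f1
from .ner import NerHyperparams, NerModel, train_ner
from .relations import RelHyperparams, RelModel, predict_relations, train_rel
from .schema import EntityCategory, RelationType
from .synthetic import GeneratorConfig, generate_corpus

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full experiment run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    split_seed: int = 0
    ner: NerHyperparams = field(default_factory=NerHyperparams)
    rel: RelHyperparams = field(default_factory=RelHyperparams)
    n_runs: int = 5
    run_dir: str | None = None

    def validate(self) -> None:
        if any(r <= 0 for r in self.split_ratios):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def echo(self) -> dict:
        d = {
            "generator": self.generator.echo(),
            "split_ratios": list(self.split_ratios),
            "split_seed": self.split_seed,
            "ner": asdict(self.ner),
            "rel": asdict(self.rel),
            "n_runs": self.n_runs,
        }
        return d


def split_corpus(
    corpus: list[AnnotatedReport],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[list[AnnotatedReport], list[AnnotatedReport], list[AnnotatedReport]]:
    """Report-level train/dev/test split; disjoint and exhaustive.

    Dev and test sizes are floor(ratio x n) with the remainder assigned
    to training.  When reports carry a ``source`` tag, each source
    stratum is split independently (e.g. chest and abdomen reports each
    get their own 70/10/20 split).
    """
    if len(corpus) < 3:
        raise ValueError("need at least 3 reports to split")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    strata: dict[str | None, list[AnnotatedReport]] = {}
    for report in corpus:
        strata.setdefault(report.source, []).append(report)
    train, dev, test = [], [], []
    for key in sorted(strata, key=lambda k: (k is None, k)):
        group = strata[key]
        order = rng.permutation(len(group))
        n = len(group)
        n_dev = int(ratios[1] * n)
        n_test = int(ratios[2] * n)
        n_train = n - n_dev - n_test
        shuffled = [group[i] for i in order]
        train += shuffled[:n_train]
        dev += shuffled[n_train : n_train + n_dev]
        test += shuffled[n_train + n_dev :]
    return train, dev, test


def run_pipeline(
    text: str,
    ner_model: NerModel,
    rel_model: RelModel,
    report_id: str = "report",
) -> AnnotatedReport:
    """Structure one raw report: segment, tag entities, classify relations."""
    report = AnnotatedReport(id=report_id, text=text)
    prepare_report(report)
    report.entities = ner_model.predict_report(report)
    report.relations = predict_relations(rel_model, report)
    report.validate()
    return report


def apply_pipeline_to_report(
    report: AnnotatedReport, ner_model: NerModel, rel_model: RelModel
) -> AnnotatedReport:
    """Run both stages on an already-prepared report (annotations ignored)."""
    pred = AnnotatedReport(
        id=report.id, text=report.text,
        sentences=report.sentences, source=report.source,
    )
    pred.entities = ner_model.predict_report(pred)
    pred.relations = predict_relations(rel_model, pred)
    return pred


def structured_records(report: AnnotatedReport) -> list[dict]:
    """One record per concept entity with modifier and evidence links."""
    records = []
    for ent in report.entities:
        if ent.type.category is not EntityCategory.CONCEPT:
            continue
        modifiers = [
            {
                "type": r.tail.type.brat_label,
                "text": r.tail.text,
                "start": r.tail.start,
                "end": r.tail.end,
            }
            for r in report.relations
            if r.type is RelationType.MODIFIER and r.head is ent
        ]
        evidence_for = [
            {"text": r.tail.text, "start": r.tail.start, "end": r.tail.end}
            for r in report.relations
            if r.type is RelationType.EVIDENCE and r.head is ent
        ]
        records.append(
            {
                "report_id": report.id,
                "concept": ent.text,
                "type": ent.type.brat_label,
                "start": ent.start,
                "end": ent.end,
                "modifiers": modifiers,
                "evidence_for": evidence_for,
            }
        )
    return records


@dataclass
class RunMetrics:
    entity: MetricsReport
    relation_gold: MetricsReport
    relation_pipeline: MetricsReport


@dataclass
class ExperimentReport:
    config_echo: dict
    runs: list[RunMetrics]
    mean_entity_f1: float
    mean_relation_gold_f1: float
    mean_pipeline_f1: float
    ner_logs: list[list[dict]]
    rel_logs: list[list[dict]]


def evaluate_models(
    ner_model: NerModel,
    rel_model: RelModel,
    test: list[AnnotatedReport],
) -> RunMetrics:
    """Three metric tables: entity F1, relation F1 (gold), pipeline F1."""
    gold_entities = [r.entities for r in test]
    gold_relations = [r.relations for r in test]
    pred_entities = [ner_model.predict_report(r) for r in test]
    rel_gold_pred = [predict_relations(rel_model, r) for r in test]
    pipeline_pred = []
    for report, ents in zip(test, pred_entities):
        tmp = AnnotatedReport(
            id=report.id, text=report.text,
            sentences=report.sentences, entities=ents,
        )
        pipeline_pred.append(predict_relations(rel_model, tmp))
    return RunMetrics(
        entity=entity_f1(gold_entities, pred_entities),
        relation_gold=relation_f1(gold_relations, rel_gold_pred, "gold_entities"),
        relation_pipeline=relation_f1(gold_relations, pipeline_pred, "pipeline"),
    )


def run_experiment(config: PipelineConfig) -> ExperimentReport:
    """Generate/split a corpus and train + evaluate both models n_runs times.

    Each run uses a distinct parameter-initialization seed; reported
    scores are means over runs.  With a run directory set, the config
    echo, per-epoch logs and metric tables are written there.
    """
    config.validate()
    corpus = generate_corpus(config.generator)
    train, dev, test = split_corpus(corpus, config.split_ratios, config.split_seed)
    logger.info(
        "corpus %d reports -> %d train / %d dev / %d test",
        len(corpus), len(train), len(dev), len(test),
    )
    runs, ner_logs, rel_logs = [], [], []
    for run_idx in range(config.n_runs):
        ner_hp = copy.deepcopy(config.ner)
        rel_hp = copy.deepcopy(config.rel)
        ner_hp.seed = config.ner.seed + 1000 * run_idx
        rel_hp.seed = config.rel.seed + 1000 * run_idx
        ner_model, ner_log = train_ner(train, dev, ner_hp)
        rel_model, rel_log = train_rel(train, dev, rel_hp)
        runs.append(evaluate_models(ner_model, rel_model, test))
        ner_logs.append(ner_log)
        rel_logs.append(rel_log)

    report = ExperimentReport(
        config_echo=config.echo(),
        runs=runs,
        mean_entity_f1=float(np.mean([r.entity.micro.f1 for r in runs])),
        mean_relation_gold_f1=float(
            np.mean([r.relation_gold.micro.f1 for r in runs])
        ),
        mean_pipeline_f1=float(
            np.mean([r.relation_pipeline.micro.f1 for r in runs])
        ),
        ner_logs=ner_logs,
        rel_logs=rel_logs,
    )
    if config.run_dir:
        _write_experiment_artifacts(config, report)
    return report


def _write_experiment_artifacts(config: PipelineConfig, report: ExperimentReport):
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(
        json.dumps(report.config_echo, indent=2), encoding="utf-8"
    )
    (run_dir / "training_logs.json").write_text(
        json.dumps({"ner": report.ner_logs, "rel": report.rel_logs}, indent=2),
        encoding="utf-8",
    )
    tables = []
    for i, run in enumerate(report.runs):
        for name, metrics in (
            ("entity", run.entity),
            ("relation_gold", run.relation_gold),
            ("relation_pipeline", run.relation_pipeline),
        ):
            frame = metrics.to_frame()
            frame.insert(0, "table", name)
            frame.insert(0, "run", i)
            tables.append(frame)
    pd.concat(tables, ignore_index=True).to_csv(
        run_dir / "metrics.tsv", sep="\t", index=False
    )
    summary = {
        "mean_entity_f1": report.mean_entity_f1,
        "mean_relation_gold_f1": report.mean_relation_gold_f1,
        "mean_pipeline_f1": report.mean_pipeline_f1,
    }
    (run_dir / "summary.json").write_text(
        json.dumps(summary, indent=2), encoding="utf-8"
    )
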