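"""BRAT standoff reading and writing.

A corpus is a directory of paired files: ``<id>.txt`` with the report
text and ``<id>.ann`` with one annotation per line.  Only entity
(T) lines and binary relation (R) lines are consumed::

    T1<TAB>Observation 8 14<TAB>nodule
    R1<TAB>Modifier Arg1:T1 Arg2:T2

Attribute/event/normalization lines (A/E/N/#) are skipped with a
warning.  Relations are stored in normalized head->tail direction
regardless of the argument order in the file.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

from .corpus import AnnotatedReport
from .schema import (
    EntitySpan,
    EntityType,
    Relation,
    RelationType,
    SchemaError,
    normalize_relation_direction,
)
from .text import (
    DEFAULT_TERMINATORS,
    Tokenizer,
    get_tokenizer,
    segment_sentences,
    tokenize_sentence,
)

logger = logging.getLogger(__name__)


class BratParseError(ValueError):
    """Malformed BRAT standoff content."""


def read_brat(
    text_document: str, annotation_document: str, report_id: str = "report"
) -> AnnotatedReport:
    """Parse a (text, .ann) pair into an :class:`AnnotatedReport`.

    Entity spans must lie inside the text and match the quoted surface
    string; relations must satisfy the schema in one orientation.  The
    returned report has no sentence structure — see
    :func:`prepare_report`.
    """
    report = AnnotatedReport(id=report_id, text=text_document)
    entities: dict[str, EntitySpan] = {}
    relation_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(annotation_document.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line[0] == "T":
            ent = _parse_entity_line(line, text_document, lineno)
            if ent.id in entities:
                raise BratParseError(f"line {lineno}: duplicate entity id {ent.id}")
            entities[ent.id] = ent
        elif line[0] == "R":
            relation_lines.append((lineno, line))
        elif line[0] in "AEN#M":
            warnings.warn(
                f"{report_id}: ignoring unsupported BRAT line {line.split()[0]}",
                stacklevel=2,
            )
        else:
            raise BratParseError(f"line {lineno}: unrecognized line {line!r}")

    report.entities = sorted(entities.values(), key=lambda e: (e.start, e.end))
    for lineno, line in relation_lines:
        report.relations.append(_parse_relation_line(line, entities, lineno))
    report.validate()
    return report


def _parse_entity_line(line: str, text: str, lineno: int) -> EntitySpan:
    parts = line.split("\t")
    if len(parts) < 3:
        raise BratParseError(f"line {lineno}: entity line needs 3 tab fields")
    tid, type_span, surface = parts[0], parts[1], parts[2]
    pieces = type_span.split()
    if len(pieces) != 3:
        if ";" in type_span:
            raise BratParseError(
                f"line {lineno}: discontinuous spans are not supported"
            )
        raise BratParseError(f"line {lineno}: malformed entity span {type_span!r}")
    type_name, start_s, end_s = pieces
    etype = EntityType.from_label(type_name)
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise BratParseError(f"line {lineno}: non-integer offsets") from None
    if not (0 <= start < end <= len(text)):
        raise BratParseError(
            f"line {lineno}: offsets [{start},{end}) outside text of "
            f"length {len(text)}"
        )
    actual = text[start:end]
    if actual != surface:
        raise BratParseError(
            f"line {lineno}: annotated text {surface!r} does not match "
            f"document substring {actual!r}"
        )
    return EntitySpan(id=tid, type=etype, start=start, end=end, text=surface)


def _parse_relation_line(
    line: str, entities: dict[str, EntitySpan], lineno: int
) -> Relation:
    parts = line.split("\t")
    if len(parts) < 2:
        raise BratParseError(f"line {lineno}: relation line needs 2 tab fields")
    rid, body = parts[0], parts[1]
    pieces = body.split()
    if len(pieces) != 3:
        raise BratParseError(f"line {lineno}: malformed relation body {body!r}")
    rtype = RelationType.from_label(pieces[0])
    args = {}
    for piece in pieces[1:]:
        key, _, val = piece.partition(":")
        args[key] = val
    if set(args) != {"Arg1", "Arg2"}:
        raise BratParseError(f"line {lineno}: expected Arg1/Arg2, got {sorted(args)}")
    try:
        arg1, arg2 = entities[args["Arg1"]], entities[args["Arg2"]]
    except KeyError as exc:
        raise BratParseError(f"line {lineno}: unknown entity id {exc}") from None
    try:
        head, tail = normalize_relation_direction(rtype, arg1, arg2)
    except SchemaError as exc:
        raise SchemaError(f"line {lineno}: {exc}") from None
    return Relation(id=rid, type=rtype, head=head, tail=tail)


def write_brat(report: AnnotatedReport) -> tuple[str, str]:
    """Serialize a report to (text document, annotation document).

    Entities are renumbered T1..Tn in span order and relations R1..Rm;
    reading the output back reproduces the report up to identifier
    renaming.
    """
    report.validate()
    lines: list[str] = []
    ids: dict[int, str] = {}
    for i, ent in enumerate(
        sorted(report.entities, key=lambda e: (e.start, e.end)), start=1
    ):
        tid = f"T{i}"
        ids[id(ent)] = tid
        lines.append(
            f"{tid}\t{ent.type.brat_label} {ent.start} {ent.end}\t{ent.text}"
        )
    for j, rel in enumerate(report.relations, start=1):
        lines.append(
            f"R{j}\t{rel.type.brat_label} "
            f"Arg1:{ids[id(rel.head)]} Arg2:{ids[id(rel.tail)]}"
        )
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return report.text, ann


def prepare_report(
    report: AnnotatedReport,
    terminators=DEFAULT_TERMINATORS,
    tokenizer: Tokenizer | str = "regex",
) -> AnnotatedReport:
    """Segment and tokenize a report in place (and return it)."""
    if isinstance(tokenizer, str):
        tokenizer = get_tokenizer(tokenizer)
    report.sentences = segment_sentences(report.text, terminators)
    for sent in report.sentences:
        tokenize_sentence(report.text, sent, tokenizer)
    return report


# ---------------------------------------------------------------------------
# Directory-level I/O


def write_corpus_dir(
    corpus: list[AnnotatedReport], directory: str | Path, manifest: dict | None = None
) -> None:
    """Write one .txt/.ann pair per report plus an optional manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for report in corpus:
        text, ann = write_brat(report)
        (directory / f"{report.id}.txt").write_text(text, encoding="utf-8")
        (directory / f"{report.id}.ann").write_text(ann, encoding="utf-8")
    if manifest is not None:
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )


def read_corpus_dir(
    directory: str | Path,
    prepare: bool = True,
    tokenizer: Tokenizer | str = "regex",
) -> list[AnnotatedReport]:
    """Read every .txt/.ann pair in a directory, sorted by report id."""
    directory = Path(directory)
    reports = []
    manifest = {}
    manifest_path = directory / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    sources = manifest.get("sources", {})
    for txt_path in sorted(directory.glob("*.txt")):
        rid = txt_path.stem
        ann_path = directory / f"{rid}.ann"
        ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        report = read_brat(txt_path.read_text(encoding="utf-8"), ann, report_id=rid)
        report.source = sources.get(rid)
        if prepare:
            prepare_report(report, tokenizer=tokenizer)
        reports.append(report)
    return reports
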