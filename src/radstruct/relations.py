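"""Relation extraction: typed candidates, span-marker encoding, classifier.

Candidates are enumerated at *report* scope after concatenating the
sentences in order (so cross-sentence relations are representable): for
the modifier relation every (concept entity, modifier entity) pair, for
the evidence relation every (observation, clinical finding) pair.  Each
candidate is rendered as the report token sequence with four entity span
tokens — typed opening/closing markers around the head and tail mention,
e.g. "a 3 cm <OBS> nodule </OBS> in the <AE> right upper lobe </AE>" —
and scored by an attention-weighted bidirectional LSTM binary
classifier.  Candidates with probability above the decision threshold
become relations.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .corpus import AnnotatedReport, Token
from .metrics import relation_f1
from .nn.layers import DTYPE, AttentionPooling, BiLSTM, Dropout, Embedding, Linear, _sigmoid
from .nn.optim import PlateauScheduler, SGDMomentum, clip_gradients
from .schema import (
    EntityCategory,
    EntitySpan,
    EntityType,
    Relation,
    RelationType,
    validate_relation,
)
from .vocab import Vocabulary, initialize_embeddings

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT = "radstruct-rel-v1"


class TruncationError(ValueError):
    """Marked entities cannot both fit in the fixed-length window."""


_MARKER_ABBREV = {
    EntityType.OBSERVATION: "OBS",
    EntityType.CLINICAL_FINDING: "CF",
    EntityType.ANATOMICAL_LOCATION: "AE",
    EntityType.CERTAINTY: "CER",
    EntityType.CHANGE: "CHG",
    EntityType.CHARACTERISTICS: "CHR",
    EntityType.SIZE: "SIZ",
}


@dataclass(frozen=True)
class MarkerVocabulary:
    """Opening/closing entity span tokens per entity type.

    Markers are atomic vocabulary items, disjoint from text tokens.
    """

    markers: dict[EntityType, tuple[str, str]] = field(
        default_factory=lambda: {
            t: (f"<{a}>", f"</{a}>") for t, a in _MARKER_ABBREV.items()
        }
    )

    def opening(self, etype: EntityType) -> str:
        return self.markers[etype][0]

    def closing(self, etype: EntityType) -> str:
        return self.markers[etype][1]

    def all_tokens(self) -> list[str]:
        return [tok for pair in self.markers.values() for tok in pair]


@dataclass
class RelationCandidate:
    """An ordered, schema-admissible entity pair for one relation type."""

    report_id: str
    rel_type: RelationType
    head: EntitySpan
    tail: EntitySpan
    label: bool | None = None
    encoded_tokens: list[str] | None = None
    score: float | None = None


def concatenate_report(report: AnnotatedReport) -> list[Token]:
    """Report-level token sequence: sentence tokens in order.

    No separator token is inserted between sentences (plain joining);
    each token keeps its character offsets, which is the index -> span
    offset map.
    """
    return [tok for sent in report.sentences for tok in sent.tokens]


def entity_token_range(tokens: list[Token], entity: EntitySpan) -> tuple[int, int]:
    """Half-open token-index range [i, j) covering the entity span."""
    first = last = None
    for i, tok in enumerate(tokens):
        if tok.end <= entity.start:
            continue
        if tok.start >= entity.end:
            break
        if first is None:
            first = i
        last = i
    if first is None:
        raise ValueError(f"entity {entity.id} matches no tokens")
    return first, last + 1


def generate_candidates(report: AnnotatedReport) -> list[RelationCandidate]:
    """Enumerate all schema-admissible entity pairs of a report.

    For MODIFIER: every (concept, modifier) pair; for EVIDENCE: every
    (observation, clinical finding) pair.  When the report carries gold
    relations, candidate labels mark which pairs are related.
    """
    has_gold = bool(report.relations)
    concepts = [e for e in report.entities if e.type.category is EntityCategory.CONCEPT]
    modifiers = [
        e for e in report.entities if e.type.category is EntityCategory.MODIFIER
    ]
    observations = [e for e in concepts if e.type is EntityType.OBSERVATION]
    findings = [e for e in concepts if e.type is EntityType.CLINICAL_FINDING]

    # Gold relations may reference equal spans under different object ids
    # (e.g. predicted entities); match by (type, span) as well.
    gold_keys = {
        (
            r.type,
            (r.head.type, r.head.start, r.head.end),
            (r.tail.type, r.tail.start, r.tail.end),
        )
        for r in report.relations
    }

    def label_of(rtype, head, tail):
        if not has_gold:
            return None
        return (
            rtype,
            (head.type, head.start, head.end),
            (tail.type, tail.start, tail.end),
        ) in gold_keys

    candidates = []
    for head in concepts:
        for tail in modifiers:
            candidates.append(
                RelationCandidate(
                    report.id, RelationType.MODIFIER, head, tail,
                    label=label_of(RelationType.MODIFIER, head, tail),
                )
            )
    for head in observations:
        for tail in findings:
            candidates.append(
                RelationCandidate(
                    report.id, RelationType.EVIDENCE, head, tail,
                    label=label_of(RelationType.EVIDENCE, head, tail),
                )
            )
    for cand in candidates:
        assert validate_relation(cand.head.type, cand.tail.type, cand.rel_type)
    candidates.sort(
        key=lambda c: (c.head.start, c.tail.start, c.rel_type.value)
    )
    return candidates


def expected_candidate_count(report: AnnotatedReport) -> int:
    """|concepts| x |modifiers| + |observations| x |findings|."""
    n_con = sum(
        1 for e in report.entities if e.type.category is EntityCategory.CONCEPT
    )
    n_mod = len(report.entities) - n_con
    n_obs = sum(1 for e in report.entities if e.type is EntityType.OBSERVATION)
    n_fin = sum(1 for e in report.entities if e.type is EntityType.CLINICAL_FINDING)
    return n_con * n_mod + n_obs * n_fin


def encode_candidate(
    tokens: list[Token],
    candidate: RelationCandidate,
    marker_vocab: MarkerVocabulary,
    max_len: int = 256,
) -> list[str]:
    """Insert 4 entity span tokens and fit the sequence to ``max_len``.

    Markers of each entity's type go immediately before/after its token
    run.  If the marked sequence exceeds ``max_len``, a window centered
    on the midpoint between the two entities is kept; both marked
    entities must survive truncation or :class:`TruncationError` is
    raised.  Raises ``ValueError`` for overlapping head/tail spans.
    """
    head, tail = candidate.head, candidate.tail
    if head.overlaps(tail):
        raise ValueError(
            f"candidate with overlapping spans {head.id}/{tail.id}"
        )
    h_range = entity_token_range(tokens, head)
    t_range = entity_token_range(tokens, tail)
    inserts: list[tuple[int, int, str]] = []  # (token idx, order, marker)
    # order: closing markers before opening ones at the same boundary index
    inserts.append((h_range[0], 1, marker_vocab.opening(head.type)))
    inserts.append((h_range[1], 0, marker_vocab.closing(head.type)))
    inserts.append((t_range[0], 1, marker_vocab.opening(tail.type)))
    inserts.append((t_range[1], 0, marker_vocab.closing(tail.type)))
    by_pos: dict[tuple[int, int], list[str]] = {}
    for pos, order, marker in sorted(inserts, key=lambda x: (x[0], x[1])):
        by_pos.setdefault((pos, order), []).append(marker)

    out: list[str] = []
    marked_positions: list[int] = []
    for i in range(len(tokens) + 1):
        for order in (0, 1):
            for marker in by_pos.get((i, order), []):
                marked_positions.append(len(out))
                out.append(marker)
        if i < len(tokens):
            out.append(tokens[i].text)

    if len(out) <= max_len:
        return out
    lo_need = min(marked_positions)
    hi_need = max(marked_positions) + 1
    if hi_need - lo_need > max_len:
        raise TruncationError(
            f"entities span {hi_need - lo_need} tokens > window {max_len}"
        )
    center = (lo_need + hi_need) // 2
    lo = center - max_len // 2
    lo = max(0, min(lo, len(out) - max_len, lo_need))
    lo = max(lo, hi_need - max_len)
    return out[lo : lo + max_len]


@dataclass
class RelHyperparams:
    embedding_dim: int = 100
    hidden_dim: int = 512
    batch_size: int = 16
    dropout: float = 0.1
    initial_lr: float = 0.1
    momentum: float = 0.9
    grad_clip: float = 5.0
    lr_decay_patience: int = 3
    lr_decay_factor: float = 0.5
    lr_floor: float = 1e-4
    max_epochs: int = 10
    max_len: int = 256
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        for name in (
            "embedding_dim", "hidden_dim", "batch_size", "initial_lr",
            "momentum", "grad_clip", "max_epochs", "max_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class RelModel:
    """Attention-weighted BiLSTM binary classifier over marked sequences."""

    def __init__(
        self,
        vocab: Vocabulary,
        hp: RelHyperparams,
        marker_vocab: MarkerVocabulary | None = None,
    ):
        self.vocab = vocab
        self.hp = hp
        self.markers = marker_vocab or MarkerVocabulary()
        rng = np.random.default_rng(hp.seed)
        self.embedding = Embedding(len(vocab), hp.embedding_dim, rng)
        self.encoder = BiLSTM(hp.embedding_dim, hp.hidden_dim, rng)
        self.attention = AttentionPooling(2 * hp.hidden_dim, rng)
        self.out = Linear(2 * hp.hidden_dim, 1, rng)
        self.drop_in = Dropout(hp.dropout)
        self.drop_out = Dropout(hp.dropout)

    def parameters(self) -> dict[str, np.ndarray]:
        out = {f"emb_{k}": v for k, v in self.embedding.params.items()}
        out.update({f"enc_{k}": v for k, v in self.encoder.parameters().items()})
        out.update({f"att_{k}": v for k, v in self.attention.params.items()})
        out.update({f"out_{k}": v for k, v in self.out.params.items()})
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {f"emb_{k}": v for k, v in self.embedding.grads.items()}
        out.update({f"enc_{k}": v for k, v in self.encoder.gradients().items()})
        out.update({f"att_{k}": v for k, v in self.attention.grads.items()})
        out.update({f"out_{k}": v for k, v in self.out.grads.items()})
        return out

    def zero_grad(self) -> None:
        self.embedding.zero_grad()
        self.encoder.zero_grad()
        self.attention.zero_grad()
        self.out.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.parameters().items():
            v[:] = state[k]

    def forward(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        rng: np.random.Generator | None = None,
        return_attention: bool = False,
    ):
        x = self.embedding.forward(ids)
        x = self.drop_in.forward(x, rng)
        h = self.encoder.forward(x, mask.astype(x.dtype))
        h = self.drop_out.forward(h, rng)
        r, alpha = self.attention.forward(h, mask)
        self._hstar = np.tanh(r)
        logits = self.out.forward(self._hstar)[:, 0]
        probs = _sigmoid(logits)
        if return_attention:
            return probs, alpha
        return probs

    def backward(self, d_logits: np.ndarray) -> None:
        d_hstar = self.out.backward(d_logits[:, None].astype(DTYPE))
        d_r = d_hstar * (1.0 - self._hstar * self._hstar)
        d_h = self.attention.backward(d_r)
        d_h = self.drop_out.backward(d_h)
        d_x = self.encoder.backward(np.ascontiguousarray(d_h))
        d_x = self.drop_in.backward(d_x)
        self.embedding.backward(d_x)

    def save(self, path: str | Path) -> None:
        meta = {
            "format": CHECKPOINT_FORMAT,
            "hyperparams": asdict(self.hp),
            "vocab": self.vocab.tokens,
            "markers": {t.name: list(p) for t, p in self.markers.markers.items()},
        }
        buf = io.BytesIO()
        np.savez(buf, **self.parameters())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "RelModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"not a {CHECKPOINT_FORMAT} checkpoint")
            arrays = np.load(io.BytesIO(zf.read("params.npz")))
            vocab = Vocabulary.__new__(Vocabulary)
            vocab.index = {t: i for i, t in enumerate(meta["vocab"])}
            vocab.tokens = list(meta["vocab"])
            markers = MarkerVocabulary(
                {EntityType[k]: tuple(v) for k, v in meta["markers"].items()}
            )
            model = cls(vocab, RelHyperparams(**meta["hyperparams"]), markers)
            model.load_state_dict({k: arrays[k] for k in arrays.files})
        return model


# ---------------------------------------------------------------------------
# Training


def _encode_corpus_candidates(
    corpus: list[AnnotatedReport],
    markers: MarkerVocabulary,
    max_len: int,
) -> tuple[list[RelationCandidate], int]:
    """Attach encoded token sequences; returns (candidates, n_truncation_failures)."""
    encoded = []
    failures = 0
    for report in corpus:
        tokens = concatenate_report(report)
        for cand in generate_candidates(report):
            if cand.head.overlaps(cand.tail):
                logger.warning(
                    "%s: skipping candidate with overlapping spans", report.id
                )
                continue
            try:
                cand.encoded_tokens = encode_candidate(tokens, cand, markers, max_len)
            except TruncationError:
                cand.encoded_tokens = None
                failures += 1
            encoded.append(cand)
    return encoded, failures


def train_rel(
    train_corpus: list[AnnotatedReport],
    dev_corpus: list[AnnotatedReport],
    hp: RelHyperparams | None = None,
    marker_vocab: MarkerVocabulary | None = None,
    pretrained_embeddings: dict[str, np.ndarray] | None = None,
) -> tuple[RelModel, list[dict]]:
    """Train the relation classifier on all generated candidates.

    Positives are the gold pairs; negatives are every other admissible
    pair — no negative down-sampling.  Returns the checkpoint with the
    best development relation micro-F1 (computed with gold entities).
    """
    hp = hp or RelHyperparams()
    hp.validate()
    markers = marker_vocab or MarkerVocabulary()
    if not train_corpus:
        raise ValueError("empty training corpus")
    candidates, n_fail = _encode_corpus_candidates(train_corpus, markers, hp.max_len)
    candidates = [c for c in candidates if c.encoded_tokens is not None]
    n_pos = sum(1 for c in candidates if c.label)
    if n_pos == 0:
        raise ValueError("no positive relation candidates in training data")
    logger.info(
        "relation training set: %d candidates (%d positive, %d truncation failures)",
        len(candidates), n_pos, n_fail,
    )

    vocab = Vocabulary.from_corpus_tokens(
        tok.text
        for report in train_corpus
        for sent in report.sentences
        for tok in sent.tokens
    )
    for marker in markers.all_tokens():
        vocab.add(marker)
    model = RelModel(vocab, hp, markers)
    if pretrained_embeddings:
        initialize_embeddings(model.embedding.params["W"], vocab, pretrained_embeddings)
    # Start the output bias at the class-prior log-odds so early updates go
    # into discrimination rather than fitting the positive rate.
    prior = n_pos / len(candidates)
    if 0.0 < prior < 1.0:
        model.out.params["b"][0] = float(np.log(prior / (1.0 - prior)))

    ids_list = [vocab.encode(c.encoded_tokens) for c in candidates]
    labels = np.array([bool(c.label) for c in candidates], dtype=DTYPE)
    lengths = [len(a) for a in ids_list]

    rng = np.random.default_rng(hp.seed + 1)
    optimizer = SGDMomentum(model.parameters(), hp.initial_lr, hp.momentum)
    scheduler = PlateauScheduler(
        optimizer, hp.lr_decay_factor, hp.lr_decay_patience, hp.lr_floor
    )
    log: list[dict] = []
    best_f1, best_state = -1.0, model.state_dict()

    from .ner import _make_batches, _pad_batch  # shared batching helpers

    for epoch in range(hp.max_epochs):
        batches = _make_batches(list(range(len(ids_list))), lengths, hp.batch_size)
        rng.shuffle(batches)
        losses = []
        for batch in batches:
            ids, mask = _pad_batch([ids_list[i] for i in batch])
            y = labels[batch]
            model.zero_grad()
            p = model.forward(ids, mask, rng=rng)
            eps = 1e-9
            loss = float(
                -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            )
            d_logits = (p - y) / len(batch)
            model.backward(d_logits)
            grads = model.gradients()
            clip_gradients(grads, hp.grad_clip)
            optimizer.step(grads)
            losses.append(loss)
        dev_f1 = evaluate_rel(model, dev_corpus) if dev_corpus else 0.0
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "dev_f1": dev_f1,
                "lr": optimizer.lr,
            }
        )
        if dev_f1 > best_f1 or not dev_corpus:
            # no dev set: keep the latest model instead of an early snapshot
            best_f1, best_state = dev_f1, model.state_dict()
        scheduler.update(dev_f1)
        if dev_f1 >= 1.0:
            break
    model.load_state_dict(best_state)
    return model, log


def score_candidates(
    model: RelModel,
    report: AnnotatedReport,
    batch_size: int = 256,
) -> list[RelationCandidate]:
    """Generate, encode and score every candidate of a report."""
    from .ner import _make_batches, _pad_batch

    tokens = concatenate_report(report)
    candidates = []
    for cand in generate_candidates(report):
        if cand.head.overlaps(cand.tail):
            logger.warning("%s: skipping overlapping candidate", report.id)
            continue
        try:
            cand.encoded_tokens = encode_candidate(
                tokens, cand, model.markers, model.hp.max_len
            )
        except TruncationError:
            cand.encoded_tokens = None
            cand.score = 0.0
            logger.warning("%s: candidate exceeds window; scored 0", report.id)
        candidates.append(cand)
    scorable = [c for c in candidates if c.encoded_tokens is not None]
    if scorable:
        ids_list = [model.vocab.encode(c.encoded_tokens) for c in scorable]
        lengths = [len(a) for a in ids_list]
        for batch in _make_batches(list(range(len(ids_list))), lengths, batch_size):
            ids, mask = _pad_batch([ids_list[i] for i in batch])
            probs = model.forward(ids, mask, rng=None)
            for row, i in enumerate(batch):
                scorable[i].score = float(probs[row])
    return candidates


def predict_relations(
    model: RelModel,
    report: AnnotatedReport,
    threshold: float | None = None,
) -> list[Relation]:
    """Relations whose candidate probability reaches the decision threshold."""
    threshold = model.hp.threshold if threshold is None else threshold
    relations = []
    for cand in score_candidates(model, report):
        if cand.score is not None and cand.score >= threshold:
            rel = Relation(
                id=f"R{len(relations) + 1}",
                type=cand.rel_type,
                head=cand.head,
                tail=cand.tail,
            )
            rel.score = cand.score
            relations.append(rel)
    return relations


def evaluate_rel(model: RelModel, corpus: list[AnnotatedReport]) -> float:
    """Relation micro-F1 on gold entities over a corpus."""
    gold = [r.relations for r in corpus]
    pred = [predict_relations(model, r) for r in corpus]
    return relation_f1(gold, pred, mode="gold_entities").micro.f1


def dump_candidates(candidates: list[RelationCandidate]) -> str:
    """Tab-separated audit dump: one line per candidate."""
    lines = ["report_id\trel_type\thead_id\ttail_id\tlabel\tscore"]
    for c in candidates:
        label = "" if c.label is None else str(int(c.label))
        score = "" if c.score is None else f"{c.score:.6f}"
        lines.append(
            f"{c.report_id}\t{c.rel_type.brat_label}\t{c.head.id}\t{c.tail.id}"
            f"\t{label}\t{score}"
        )
    return "\n".join(lines) + "\n"
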