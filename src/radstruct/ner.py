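"""Entity extraction: BiLSTM-CRF sequence labeler over IOB2 tags.

Tokens are embedded (optionally initialized from a pretrained word2vec
text file), encoded by a bidirectional LSTM with dropout on its input
and output vectors, projected to per-tag emission scores, and decoded by
a linear-chain CRF.  Training is minibatch SGD with momentum, gradient
clipping and decay-on-plateau of the learning rate monitored on the
development-set entity-level micro-F1; the checkpoint with the best
development score is returned.
"""

from __future__ import annotations

import json
import zipfile
import io
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .corpus import AnnotatedReport
from .iob2 import TAGS, TAG_TO_INDEX, decode_iob2, encode_iob2
from .metrics import entity_f1
from .nn.crf import (
    batched_gold_score,
    crf_forward_backward,
    viterbi_decode,
)
from .nn.layers import DTYPE, BiLSTM, Dropout, Embedding, Linear
from .nn.optim import PlateauScheduler, SGDMomentum, clip_gradients
from .schema import EntitySpan
from .vocab import Vocabulary, initialize_embeddings

CHECKPOINT_FORMAT = "radstruct-ner-v1"


@dataclass
class NerHyperparams:
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
    max_epochs: int = 30
    unk_dropout: float = 0.01
    hard_transition_mask: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for name in (
            "embedding_dim", "hidden_dim", "batch_size", "initial_lr",
            "momentum", "grad_clip", "lr_decay_patience", "lr_decay_factor",
            "max_epochs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _invalid_transition_mask() -> np.ndarray:
    """(K+1, K) boolean mask of IOB2-invalid transitions; row K is <start>."""
    K = len(TAGS)
    bad = np.zeros((K + 1, K), dtype=bool)
    for j, tag_j in enumerate(TAGS):
        if not tag_j.startswith("I-"):
            continue
        ttype = tag_j[2:]
        for i, tag_i in enumerate(TAGS):
            if tag_i[2:] != ttype or tag_i == "O":
                bad[i, j] = True
        bad[K, j] = True  # start -> I-t
    return bad


class NerModel:
    """BiLSTM-CRF tagger: parameters, encoding, decoding, persistence."""

    def __init__(self, vocab: Vocabulary, hp: NerHyperparams):
        self.vocab = vocab
        self.hp = hp
        rng = np.random.default_rng(hp.seed)
        K = len(TAGS)
        self.embedding = Embedding(len(vocab), hp.embedding_dim, rng)
        self.encoder = BiLSTM(hp.embedding_dim, hp.hidden_dim, rng)
        self.out = Linear(2 * hp.hidden_dim, K, rng)
        self.transitions = 0.01 * rng.standard_normal((K, K)).astype(DTYPE)
        self.start_scores = 0.01 * rng.standard_normal(K).astype(DTYPE)
        self.end_scores = 0.01 * rng.standard_normal(K).astype(DTYPE)
        self._crf_grads = {
            "crf_trans": np.zeros((K, K), dtype=DTYPE),
            "crf_start": np.zeros(K, dtype=DTYPE),
            "crf_end": np.zeros(K, dtype=DTYPE),
        }
        self.drop_in = Dropout(hp.dropout)
        self.drop_out = Dropout(hp.dropout)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {f"emb_{k}": v for k, v in self.embedding.params.items()}
        out.update({f"enc_{k}": v for k, v in self.encoder.parameters().items()})
        out.update({f"out_{k}": v for k, v in self.out.params.items()})
        out["crf_trans"] = self.transitions
        out["crf_start"] = self.start_scores
        out["crf_end"] = self.end_scores
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {f"emb_{k}": v for k, v in self.embedding.grads.items()}
        out.update({f"enc_{k}": v for k, v in self.encoder.gradients().items()})
        out.update({f"out_{k}": v for k, v in self.out.grads.items()})
        out.update(self._crf_grads)
        return out

    def zero_grad(self) -> None:
        self.embedding.zero_grad()
        self.encoder.zero_grad()
        self.out.zero_grad()
        for g in self._crf_grads.values():
            g[:] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.parameters().items():
            v[:] = state[k]

    # -- forward/backward ---------------------------------------------------
    def emissions(
        self, ids: np.ndarray, mask: np.ndarray, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        x = self.embedding.forward(ids)
        x = self.drop_in.forward(x, rng)
        h = self.encoder.forward(x, mask.astype(x.dtype))
        h = self.drop_out.forward(h, rng)
        return self.out.forward(h)

    def backward_from_emissions(self, d_em: np.ndarray) -> None:
        dh = self.out.backward(d_em.astype(DTYPE))
        dh = self.drop_out.backward(dh)
        dx = self.encoder.backward(np.ascontiguousarray(dh))
        dx = self.drop_in.backward(dx)
        self.embedding.backward(dx)

    # -- decoding -----------------------------------------------------------
    def _decode_transitions(self) -> tuple[np.ndarray, np.ndarray]:
        trans = self.transitions.astype(np.float64)
        start = self.start_scores.astype(np.float64)
        if self.hp.hard_transition_mask:
            bad = _invalid_transition_mask()
            trans = np.where(bad[:-1], -1e4, trans)
            start = np.where(bad[-1], -1e4, start)
        return trans, start

    def decode(self, emissions_row: np.ndarray) -> list[str]:
        trans, start = self._decode_transitions()
        path = viterbi_decode(emissions_row, trans, start, self.end_scores)
        return [TAGS[i] for i in path]

    def predict_report(self, report: AnnotatedReport) -> list[EntitySpan]:
        """Viterbi-decode every sentence and return schema-valid spans."""
        out: list[EntitySpan] = []
        sents = [s for s in report.sentences if s.tokens]
        if not sents:
            return out
        batches = _make_batches(
            list(range(len(sents))), [len(s.tokens) for s in sents], 128
        )
        for batch in batches:
            ids, mask = _pad_batch(
                [self.vocab.encode([t.text for t in sents[i].tokens]) for i in batch]
            )
            em = self.emissions(ids, mask, rng=None)
            for row, i in enumerate(batch):
                L = len(sents[i].tokens)
                tags = self.decode(em[row, :L])
                for ent in decode_iob2(report.text, sents[i], tags):
                    ent.id = f"T{len(out) + 1}"
                    out.append(ent)
        return out

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: parameters + vocab + config echo."""
        meta = {
            "format": CHECKPOINT_FORMAT,
            "hyperparams": asdict(self.hp),
            "vocab": self.vocab.tokens,
        }
        buf = io.BytesIO()
        np.savez(buf, **self.parameters())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "NerModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"not a {CHECKPOINT_FORMAT} checkpoint")
            arrays = np.load(io.BytesIO(zf.read("params.npz")))
            vocab = Vocabulary.__new__(Vocabulary)
            vocab.index = {t: i for i, t in enumerate(meta["vocab"])}
            vocab.tokens = list(meta["vocab"])
            model = cls(vocab, NerHyperparams(**meta["hyperparams"]))
            model.load_state_dict({k: arrays[k] for k in arrays.files})
        return model


# ---------------------------------------------------------------------------
# Training


def _pad_batch(id_arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    B = len(id_arrays)
    T = max(len(a) for a in id_arrays)
    ids = np.zeros((B, T), dtype=np.int64)
    mask = np.zeros((B, T), dtype=DTYPE)
    for b, a in enumerate(id_arrays):
        ids[b, : len(a)] = a
        mask[b, : len(a)] = 1.0
    return ids, mask


def _make_batches(
    indices: list[int], lengths: list[int], batch_size: int
) -> list[list[int]]:
    """Group indices into batches of similar length (less padding waste)."""
    order = sorted(indices, key=lambda i: lengths[i])
    return [order[i : i + batch_size] for i in range(0, len(order), batch_size)]


def _corpus_sentences(corpus: list[AnnotatedReport]):
    for report in corpus:
        for sent in report.sentences:
            if sent.tokens:
                yield report, sent


def train_ner(
    train_corpus: list[AnnotatedReport],
    dev_corpus: list[AnnotatedReport],
    hp: NerHyperparams | None = None,
    pretrained_embeddings: dict[str, np.ndarray] | None = None,
) -> tuple[NerModel, list[dict]]:
    """Train a BiLSTM-CRF tagger; returns (best-dev model, per-epoch log).

    Every sentence of every training report is one instance.  The log
    records mean training loss, development entity-level micro-F1 and the
    learning rate per epoch.  Fixed hyperparameter seed => reproducible.
    """
    hp = hp or NerHyperparams()
    hp.validate()
    if not train_corpus:
        raise ValueError("empty training corpus")
    vocab = Vocabulary.from_corpus_tokens(
        tok.text for _, sent in _corpus_sentences(train_corpus) for tok in sent.tokens
    )
    model = NerModel(vocab, hp)
    if pretrained_embeddings:
        initialize_embeddings(
            model.embedding.params["W"], vocab, pretrained_embeddings
        )

    instances = []
    for report, sent in _corpus_sentences(train_corpus):
        tags = encode_iob2(sent, report.entities)
        instances.append(
            (
                vocab.encode([t.text for t in sent.tokens]),
                np.array([TAG_TO_INDEX[t] for t in tags], dtype=np.int64),
            )
        )
    lengths = [len(ids) for ids, _ in instances]

    rng = np.random.default_rng(hp.seed + 1)
    optimizer = SGDMomentum(model.parameters(), hp.initial_lr, hp.momentum)
    scheduler = PlateauScheduler(
        optimizer, hp.lr_decay_factor, hp.lr_decay_patience, hp.lr_floor
    )
    unk_index = 1
    log: list[dict] = []
    best_f1, best_state = -1.0, model.state_dict()

    for epoch in range(hp.max_epochs):
        batches = _make_batches(list(range(len(instances))), lengths, hp.batch_size)
        rng.shuffle(batches)
        losses = []
        for batch in batches:
            ids, mask = _pad_batch([instances[i][0] for i in batch])
            tags, _ = _pad_batch([instances[i][1] for i in batch])
            if hp.unk_dropout > 0:
                drop = (rng.random(ids.shape) < hp.unk_dropout) & (ids > 1)
                ids = np.where(drop, unk_index, ids)
            losses.append(_train_step(model, optimizer, ids, mask, tags, rng, hp))
        dev_f1 = evaluate_ner(model, dev_corpus) if dev_corpus else 0.0
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
        if dev_f1 >= 1.0:  # metric at ceiling; nothing left to improve
            break
    model.load_state_dict(best_state)
    return model, log


def _train_step(model, optimizer, ids, mask, tags, rng, hp) -> float:
    B = ids.shape[0]
    model.zero_grad()
    em = model.emissions(ids, mask, rng=rng)
    logZ, marginals, exp_trans, start_marg, end_marg = crf_forward_backward(
        em, mask, model.transitions, model.start_scores, model.end_scores
    )
    gold = batched_gold_score(
        em, mask, model.transitions, model.start_scores, model.end_scores, tags
    )
    loss = float(np.mean(logZ - gold))

    onehot = np.zeros_like(marginals)
    B_idx, T_idx = np.nonzero(mask)
    onehot[B_idx, T_idx, tags[B_idx, T_idx]] = 1.0
    d_em = (marginals - onehot) / B
    gold_trans = np.zeros_like(exp_trans)
    if ids.shape[1] > 1:
        valid = mask[:, 1:] > 0
        np.add.at(gold_trans, (tags[:, :-1][valid], tags[:, 1:][valid]), 1.0)
    model._crf_grads["crf_trans"][:] = (exp_trans - gold_trans) / B
    lengths = mask.sum(axis=1).astype(int)
    d_start = start_marg.copy()
    d_end = end_marg.copy()
    bi = np.arange(B)
    np.add.at(d_start, (bi, tags[:, 0]), -1.0)
    np.add.at(d_end, (bi, tags[bi, lengths - 1]), -1.0)
    model._crf_grads["crf_start"][:] = d_start.sum(axis=0) / B
    model._crf_grads["crf_end"][:] = d_end.sum(axis=0) / B

    model.backward_from_emissions(d_em)
    grads = model.gradients()
    clip_gradients(grads, hp.grad_clip)
    optimizer.step(grads)
    return loss


def evaluate_ner(model: NerModel, corpus: list[AnnotatedReport]) -> float:
    """Entity-level micro-F1 of the model's predictions on a corpus."""
    gold = [r.entities for r in corpus]
    pred = [model.predict_report(r) for r in corpus]
    return entity_f1(gold, pred).micro.f1


def predict_entities(model: NerModel, report: AnnotatedReport) -> list[EntitySpan]:
    """Predict entity spans for a segmented, tokenized report."""
    return model.predict_report(report)
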