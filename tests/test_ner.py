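"""Entity extractor: training behavior, decoding contracts, persistence."""

import numpy as np
import pytest

from radstruct.brat import prepare_report
from radstruct.corpus import AnnotatedReport
from radstruct.ner import NerHyperparams, NerModel, train_ner
from radstruct.synthetic import GeneratorConfig, generate_corpus

TINY = NerHyperparams(
    embedding_dim=24, hidden_dim=24, batch_size=8, max_epochs=2, seed=3
)


@pytest.fixture(scope="module")
def micro_corpus():
    return generate_corpus(GeneratorConfig(n_reports=6, seed=21))


def test_empty_training_corpus_rejected():
    with pytest.raises(ValueError):
        train_ner([], [], TINY)


def test_loss_decreases_on_one_report(micro_corpus):
    hp = NerHyperparams(
        embedding_dim=24, hidden_dim=24, batch_size=4, max_epochs=3, seed=3
    )
    _, log = train_ner(micro_corpus[:1], [], hp)
    assert log[-1]["train_loss"] < log[0]["train_loss"]


def test_overfit_single_report_recovers_gold(micro_corpus):
    """After convergence on one report, it is decoded exactly."""
    report = micro_corpus[0]
    hp = NerHyperparams(
        embedding_dim=32, hidden_dim=32, batch_size=4, max_epochs=30,
        dropout=0.0, unk_dropout=0.0, seed=5,
    )
    model, _ = train_ner([report], [report], hp)
    pred = model.predict_report(report)
    assert sorted((e.type.name, e.start, e.end) for e in pred) == sorted(
        (e.type.name, e.start, e.end) for e in report.entities
    )


def test_lr_decay_schedule_logged(micro_corpus):
    """With a flat dev score, the LR halves every `patience` epochs."""
    hp = NerHyperparams(
        embedding_dim=16, hidden_dim=16, batch_size=8, max_epochs=6,
        lr_decay_patience=2, seed=3,
    )
    _, log = train_ner(micro_corpus[:2], [], hp)  # dev_f1 constant at 0
    assert [round(e["lr"], 4) for e in log] == [0.1, 0.1, 0.1, 0.05, 0.05, 0.025]


def test_predict_empty_report():
    model_corpus = generate_corpus(GeneratorConfig(n_reports=2, seed=9))
    model, _ = train_ner(model_corpus, [], TINY)
    empty = prepare_report(AnnotatedReport(id="e", text=""))
    assert model.predict_report(empty) == []


def test_out_of_vocabulary_tokens_do_not_error(micro_corpus):
    model, _ = train_ner(micro_corpus[:2], [], TINY)
    report = prepare_report(
        AnnotatedReport(id="oov", text="a zzzz qqqq in the wwww .")
    )
    preds = model.predict_report(report)  # must not raise
    for e in preds:
        e.validate(report.text)


def test_predictions_schema_valid(micro_corpus):
    model, _ = train_ner(micro_corpus[:4], [], TINY)
    for report in micro_corpus[4:]:
        for ent in model.predict_report(report):
            ent.validate(report.text)
            assert 0 <= ent.start < ent.end <= len(report.text)


def test_training_deterministic_for_fixed_seed(micro_corpus):
    _, log_a = train_ner(micro_corpus[:2], micro_corpus[2:3], TINY)
    _, log_b = train_ner(micro_corpus[:2], micro_corpus[2:3], TINY)
    assert log_a == log_b


def test_checkpoint_round_trip(tmp_path, micro_corpus):
    model, _ = train_ner(micro_corpus[:2], [], TINY)
    path = tmp_path / "ner.ckpt"
    model.save(path)
    loaded = NerModel.load(path)
    report = micro_corpus[3]
    assert [
        (e.type, e.start, e.end) for e in loaded.predict_report(report)
    ] == [(e.type, e.start, e.end) for e in model.predict_report(report)]


def test_embedding_dimension_mismatch_rejected(micro_corpus):
    vectors = {"a": np.zeros(7, dtype=np.float32)}
    with pytest.raises(ValueError):
        train_ner(micro_corpus[:1], [], TINY, pretrained_embeddings=vectors)


def test_pretrained_vectors_are_used(micro_corpus):
    vec = np.full(24, 0.5, dtype=np.float32)
    hp = NerHyperparams(
        embedding_dim=24, hidden_dim=16, batch_size=8, max_epochs=1,
        initial_lr=1e-9, seed=3,
    )
    model, _ = train_ner(micro_corpus[:1], [], hp, {"a": vec})
    idx = model.vocab.index["a"]
    assert np.allclose(model.embedding.params["W"][idx], 0.5, atol=1e-3)


def test_hard_transition_mask_blocks_invalid_bigrams():
    """With hard masking, decoded paths contain no IOB2-invalid bigrams."""
    from radstruct.iob2 import TAGS
    from radstruct.vocab import Vocabulary

    hp = NerHyperparams(
        embedding_dim=8, hidden_dim=8, hard_transition_mask=True, seed=12
    )
    model = NerModel(Vocabulary(["a", "b"]), hp)
    # random (untrained) scores would freely produce invalid transitions
    rng = np.random.default_rng(0)
    for _ in range(20):
        em = rng.normal(size=(6, len(TAGS))) * 5
        tags = model.decode(em)
        prev = None
        for tag in tags:
            if tag.startswith("I-"):
                assert prev is not None and prev[2:] == tag[2:] and prev != "O"
            prev = tag
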