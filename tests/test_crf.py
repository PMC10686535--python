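"""CRF correctness against brute-force path enumeration."""

import itertools

import numpy as np
import pytest

from radstruct.iob2 import TAGS
from radstruct.nn.crf import (
    batched_gold_score,
    crf_forward_backward,
    crf_log_likelihood,
    log_partition,
    path_score,
    viterbi_decode,
)


def _brute_force_scores(em, tr, st, en):
    T, K = em.shape
    return {
        path: path_score(em, tr, st, en, path)
        for path in itertools.product(range(K), repeat=T)
    }


def test_uniform_single_token_likelihood_closed_form():
    """One token, all-zero scores over the 15-tag set: logZ = log 15."""
    K = len(TAGS)
    em = np.zeros((1, K))
    zeros = np.zeros(K)
    ll = crf_log_likelihood(em, np.zeros((K, K)), zeros, zeros, [0])
    assert np.isclose(ll, -np.log(K))


@pytest.mark.parametrize("T,K", [(2, 4), (3, 5), (4, 5), (4, 15)])
def test_log_partition_matches_enumeration(T, K, rng):
    em = rng.normal(size=(T, K))
    tr = rng.normal(size=(K, K))
    st, en = rng.normal(size=K), rng.normal(size=K)
    scores = list(_brute_force_scores(em, tr, st, en).values())
    expected = np.logaddexp.reduce(scores)
    assert abs(log_partition(em, tr, st, en) - expected) < 1e-6


def test_log_likelihood_never_positive(rng):
    for _ in range(50):
        T, K = int(rng.integers(1, 6)), int(rng.integers(2, 8))
        em = rng.normal(size=(T, K)) * 3
        tr = rng.normal(size=(K, K))
        st, en = rng.normal(size=K), rng.normal(size=K)
        tags = rng.integers(0, K, size=T)
        assert crf_log_likelihood(em, tr, st, en, tags) <= 1e-9


def test_viterbi_matches_exhaustive_argmax(rng):
    """200 random instances of length <= 5: Viterbi attains the max score."""
    for _ in range(200):
        T, K = int(rng.integers(1, 6)), int(rng.integers(2, 6))
        em = rng.normal(size=(T, K))
        tr = rng.normal(size=(K, K))
        st, en = rng.normal(size=K), rng.normal(size=K)
        best = max(_brute_force_scores(em, tr, st, en).values())
        got = path_score(em, tr, st, en, viterbi_decode(em, tr, st, en))
        assert abs(got - best) < 1e-9


def test_viterbi_score_at_least_gold_path(rng):
    for _ in range(50):
        T, K = int(rng.integers(1, 7)), 6
        em = rng.normal(size=(T, K))
        tr = rng.normal(size=(K, K))
        st, en = rng.normal(size=K), rng.normal(size=K)
        gold = rng.integers(0, K, size=T)
        vit = viterbi_decode(em, tr, st, en)
        assert path_score(em, tr, st, en, vit) >= path_score(
            em, tr, st, en, gold
        ) - 1e-9


def test_forbidden_transition_never_decoded(rng):
    """With transitions[i, j] = -inf-like, the bigram (i, j) never appears."""
    K = 5
    tr = rng.normal(size=(K, K))
    tr[0, 2] = -1e9  # forbid 0 -> 2
    for _ in range(50):
        em = rng.normal(size=(int(rng.integers(2, 8)), K)) * 5
        path = viterbi_decode(em, tr, rng.normal(size=K), rng.normal(size=K))
        assert all(not (a == 0 and b == 2) for a, b in zip(path, path[1:]))


def test_empty_sentence_decodes_empty():
    assert viterbi_decode(np.zeros((0, 5)), np.zeros((5, 5)),
                          np.zeros(5), np.zeros(5)) == []


def test_batched_marginals_match_single(rng):
    """Batched forward-backward agrees with per-sentence enumeration."""
    B, T, K = 3, 4, 4
    em = rng.normal(size=(B, T, K))
    mask = np.ones((B, T))
    mask[1, 2:] = 0
    mask[2, 3:] = 0
    tr = rng.normal(size=(K, K))
    st, en = rng.normal(size=K), rng.normal(size=K)
    logZ, marginals, _, _, _ = crf_forward_backward(em, mask, tr, st, en)
    for b in range(B):
        L = int(mask[b].sum())
        scores = _brute_force_scores(em[b, :L], tr, st, en)
        total = np.logaddexp.reduce(list(scores.values()))
        assert abs(logZ[b] - total) < 1e-8
        for t in range(L):
            for k in range(K):
                p = np.exp(
                    np.logaddexp.reduce(
                        [s for path, s in scores.items() if path[t] == k]
                    )
                    - total
                )
                assert abs(marginals[b, t, k] - p) < 1e-8


def test_batched_gold_score_matches_single(rng):
    B, T, K = 4, 5, 6
    em = rng.normal(size=(B, T, K))
    mask = np.ones((B, T))
    mask[0, 3:] = 0
    tr = rng.normal(size=(K, K))
    st, en = rng.normal(size=K), rng.normal(size=K)
    tags = rng.integers(0, K, size=(B, T))
    scores = batched_gold_score(em, mask, tr, st, en, tags)
    for b in range(B):
        L = int(mask[b].sum())
        assert abs(
            scores[b] - path_score(em[b, :L], tr, st, en, tags[b, :L])
        ) < 1e-9
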