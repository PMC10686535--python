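"""Linear-chain CRF: log-likelihood, forward-backward, Viterbi decoding.

Scores for a tag path y over a sentence of length T are

    score(y) = start[y_0] + sum_t emissions[t, y_t]
             + sum_t transitions[y_t, y_{t+1}] + end[y_{T-1}]

and the log-likelihood of a gold path is score(gold) - log Z with the
log-partition Z computed by the forward algorithm in log space.  The
batched forward-backward returns the posterior marginals and expected
transition counts that make up the analytic gradient of log Z.

Internals run in float64 so that the log-partition matches brute-force
path enumeration to tight tolerance.
"""

from __future__ import annotations

import numpy as np


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.exp(a - m_safe).sum(axis=axis)) + np.squeeze(m_safe, axis=axis)
    return out


def log_partition(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
) -> float:
    """Forward-algorithm log Z for a single sentence (T, K)."""
    em = np.asarray(emissions, dtype=np.float64)
    T, K = em.shape
    if T == 0:
        return 0.0
    alpha = start.astype(np.float64) + em[0]
    for t in range(1, T):
        alpha = _logsumexp(
            alpha[:, None] + transitions.astype(np.float64) + em[t][None, :], axis=0
        )
    return float(_logsumexp(alpha + end.astype(np.float64), axis=0))


def path_score(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    tags: np.ndarray,
) -> float:
    tags = np.asarray(tags, dtype=int)
    T = len(tags)
    if T == 0:
        return 0.0
    s = float(start[tags[0]]) + float(end[tags[-1]])
    s += float(np.asarray(emissions)[np.arange(T), tags].sum())
    if T > 1:
        s += float(np.asarray(transitions)[tags[:-1], tags[1:]].sum())
    return s


def crf_log_likelihood(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    tags: np.ndarray,
) -> float:
    """log P(tags | emissions) = score(tags) - log Z; always <= 0."""
    em = np.asarray(emissions)
    if em.shape[0] != len(tags):
        raise ValueError(
            f"{em.shape[0]} emission rows for {len(tags)} tags"
        )
    return path_score(em, transitions, start, end, tags) - log_partition(
        em, transitions, start, end
    )


def viterbi_decode(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
) -> list[int]:
    """Highest-scoring tag path; ties resolve to the lowest tag index."""
    em = np.asarray(emissions, dtype=np.float64)
    T, K = em.shape if em.ndim == 2 else (0, 0)
    if T == 0:
        return []
    trans = np.asarray(transitions, dtype=np.float64)
    delta = start.astype(np.float64) + em[0]
    back: list[np.ndarray] = []
    for t in range(1, T):
        scores = delta[:, None] + trans  # (K_prev, K)
        best_prev = scores.argmax(axis=0)  # first max -> lowest index
        back.append(best_prev)
        delta = scores[best_prev, np.arange(K)] + em[t]
    delta = delta + end.astype(np.float64)
    last = int(delta.argmax())
    path = [last]
    for bp in reversed(back):
        last = int(bp[last])
        path.append(last)
    path.reverse()
    return path


# ---------------------------------------------------------------------------
# Batched training path


def crf_forward_backward(
    emissions: np.ndarray,
    mask: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
):
    """Batched posterior marginals and expected transition counts.

    Parameters: ``emissions`` (B, T, K); ``mask`` (B, T) with at least one
    valid position per row.  Returns (logZ (B,), marginals (B, T, K),
    expected_transitions (K, K) summed over batch, start_marginals (B, K),
    end_marginals (B, K)).
    """
    em = np.asarray(emissions, dtype=np.float64)
    B, T, K = em.shape
    trans = np.asarray(transitions, dtype=np.float64)
    startf = start.astype(np.float64)
    endf = end.astype(np.float64)
    m = np.asarray(mask, dtype=np.float64)
    lengths = m.sum(axis=1).astype(int)

    alphas = np.empty((B, T, K))
    alpha = startf[None, :] + em[:, 0]
    alphas[:, 0] = alpha
    for t in range(1, T):
        cand = _logsumexp(alpha[:, :, None] + trans[None] + em[:, t][:, None, :], axis=1)
        mt = m[:, t : t + 1]
        alpha = mt * cand + (1.0 - mt) * alpha
        alphas[:, t] = alpha
    logZ = _logsumexp(alpha + endf[None, :], axis=1)

    betas = np.empty((B, T, K))
    beta = np.broadcast_to(endf, (B, K)).copy()
    betas[:, T - 1] = beta
    for t in range(T - 2, -1, -1):
        cand = _logsumexp(
            trans[None] + em[:, t + 1][:, None, :] + beta[:, None, :], axis=2
        )
        mt = m[:, t + 1 : t + 2]
        beta = mt * cand + (1.0 - mt) * beta
        betas[:, t] = beta

    marginals = np.exp(alphas + betas - logZ[:, None, None]) * m[:, :, None]

    expected_trans = np.zeros((K, K))
    for t in range(T - 1):
        valid = m[:, t + 1] > 0
        if not valid.any():
            break
        joint = (
            alphas[valid, t][:, :, None]
            + trans[None]
            + em[valid, t + 1][:, None, :]
            + betas[valid, t + 1][:, None, :]
            - logZ[valid][:, None, None]
        )
        expected_trans += np.exp(joint).sum(axis=0)

    start_marg = marginals[:, 0]
    end_marg = marginals[np.arange(B), lengths - 1]
    return logZ, marginals, expected_trans, start_marg, end_marg


def batched_gold_score(
    emissions: np.ndarray,
    mask: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    tags: np.ndarray,
) -> np.ndarray:
    """Path scores of gold tag matrices (B, T) under the mask."""
    em = np.asarray(emissions, dtype=np.float64)
    B, T, K = em.shape
    m = np.asarray(mask, dtype=np.float64)
    lengths = m.sum(axis=1).astype(int)
    bi = np.arange(B)
    score = start.astype(np.float64)[tags[:, 0]]
    score = score + end.astype(np.float64)[tags[bi, lengths - 1]]
    emit = em[bi[:, None], np.arange(T)[None, :], tags] * m
    score = score + emit.sum(axis=1)
    if T > 1:
        tr = np.asarray(transitions, dtype=np.float64)[tags[:, :-1], tags[:, 1:]]
        score = score + (tr * m[:, 1:]).sum(axis=1)
    return score
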