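"""Token vocabulary and word-embedding file loading."""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import numpy as np

PAD = "<pad>"
UNK = "<unk>"


class Vocabulary:
    """Token -> index map with reserved padding (0) and unknown (1) slots."""

    def __init__(self, tokens: list[str]):
        self.index: dict[str, int] = {PAD: 0, UNK: 1}
        for tok in tokens:
            if tok not in self.index:
                self.index[tok] = len(self.index)
        self.tokens = list(self.index)

    @classmethod
    def from_corpus_tokens(
        cls, token_iter: Iterable[str], min_count: int = 1
    ) -> "Vocabulary":
        counts = Counter(token_iter)
        kept = [t for t, c in counts.items() if c >= min_count]
        return cls(sorted(kept))

    def add(self, token: str) -> int:
        if token not in self.index:
            self.index[token] = len(self.index)
            self.tokens.append(token)
        return self.index[token]

    def encode(self, words: Iterable[str]) -> np.ndarray:
        unk = self.index[UNK]
        return np.array([self.index.get(w, unk) for w in words], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index


def load_word_embeddings(path) -> dict[str, np.ndarray]:
    """Read a word2vec-style text file: token then whitespace-separated floats.

    A first line of the form "<count> <dim>" (two integers) is treated as
    a header and skipped.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        parts = first.split()
        if not (len(parts) == 2 and all(p.lstrip("-").isdigit() for p in parts)):
            if parts:
                vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float32)
        for line in fh:
            parts = line.split()
            if parts:
                vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float32)
    dims = {v.shape[0] for v in vectors.values()}
    if len(dims) > 1:
        raise ValueError(f"inconsistent embedding dimensions in file: {sorted(dims)}")
    return vectors


def initialize_embeddings(
    table: np.ndarray, vocab: Vocabulary, vectors: dict[str, np.ndarray]
) -> int:
    """Overwrite rows of ``table`` for tokens present in ``vectors``.

    Returns the number of initialized rows; raises on dimension mismatch.
    """
    if not vectors:
        return 0
    dim = next(iter(vectors.values())).shape[0]
    if dim != table.shape[1]:
        raise ValueError(
            f"embedding file dimension {dim} != model dimension {table.shape[1]}"
        )
    hits = 0
    for tok, idx in vocab.index.items():
        vec = vectors.get(tok)
        if vec is not None:
            table[idx] = vec.astype(table.dtype)
            hits += 1
    return hits
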