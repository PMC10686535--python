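"""Sentence segmentation and tokenization.

Segmentation is rule based: a configurable set of terminator patterns
(defaults: the Japanese full stop 。, newline, ASCII ".") splits the
report into sentence spans.  Tokenizers are pluggable — any callable
mapping text to a token list can be registered; the default is a
regex word/punctuation tokenizer, which is sufficient for the synthetic
corpus and for whitespace-delimited clinical text.  A morphological
analyzer (e.g. a MeCab wrapper) can be registered for Japanese input
without touching the rest of the pipeline.
"""

from __future__ import annotations

import re
import unicodedata
from typing import Callable, Iterable

from .corpus import Sentence, Token

#: Default sentence-terminator characters.
DEFAULT_TERMINATORS = ("。", "\n", ".")


def segment_sentences(
    text: str, terminators: Iterable[str] = DEFAULT_TERMINATORS
) -> list[Sentence]:
    """Split ``text`` into ordered, non-overlapping sentence spans.

    Each span ends just after a terminator character (or at end of text)
    and is trimmed of surrounding whitespace.  Whitespace-only segments
    are dropped, so the concatenation of the spans reconstructs the text
    minus inter-span whitespace.
    """
    term_set = set(terminators)
    spans: list[Sentence] = []
    seg_start = 0
    i = 0
    n = len(text)
    while i < n:
        if text[i] in term_set:
            _append_trimmed(spans, text, seg_start, i + 1)
            seg_start = i + 1
        i += 1
    _append_trimmed(spans, text, seg_start, n)
    return spans


def _append_trimmed(spans: list[Sentence], text: str, start: int, end: int) -> None:
    seg = text[start:end]
    lstrip = len(seg) - len(seg.lstrip())
    rstrip = len(seg) - len(seg.rstrip())
    start += lstrip
    end -= rstrip
    if start < end:
        spans.append(Sentence(start=start, end=end))


_WORD_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def regex_tokenize(text: str) -> list[Token]:
    """Default tokenizer: maximal word runs and single punctuation marks."""
    return [Token(m.start(), m.end(), m.group()) for m in _WORD_RE.finditer(text)]


def whitespace_tokenize(text: str) -> list[Token]:
    toks = []
    for m in re.finditer(r"\S+", text):
        toks.append(Token(m.start(), m.end(), m.group()))
    return toks


Tokenizer = Callable[[str], list[Token]]

_TOKENIZERS: dict[str, Tokenizer] = {
    "regex": regex_tokenize,
    "whitespace": whitespace_tokenize,
}


def register_tokenizer(name: str, fn: Tokenizer) -> None:
    """Register a tokenizer plug-in (text -> Token list, offsets local)."""
    _TOKENIZERS[name] = fn


def get_tokenizer(name: str) -> Tokenizer:
    try:
        return _TOKENIZERS[name]
    except KeyError:
        raise KeyError(
            f"unknown tokenizer {name!r}; registered: {sorted(_TOKENIZERS)}"
        ) from None


def tokenize_sentence(text: str, sentence: Sentence, tokenizer: Tokenizer) -> None:
    """Fill ``sentence.tokens`` by running ``tokenizer`` on its span.

    Token offsets returned by the tokenizer are local to the span and are
    shifted to report-level character offsets.
    """
    local = tokenizer(text[sentence.start : sentence.end])
    sentence.tokens = [
        Token(t.start + sentence.start, t.end + sentence.start, t.text) for t in local
    ]


def is_punctuation(token_text: str) -> bool:
    """True if the token consists solely of Unicode punctuation/symbols."""
    return len(token_text) > 0 and all(
        unicodedata.category(ch).startswith(("P", "S")) for ch in token_text
    )
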