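"""Shared tokenization helpers.

One canonical word tokenizer is used across the embedding backend, the
lexicon counters, RAKE and the n-gram builders so that "normalized
occurrence" denominators agree between stages. Whitespace counting (used
for corpus summaries and verbosity) is deliberately separate: a word count
should not depend on how punctuation is attached.
"""

from __future__ import annotations

import re

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

STOPWORDS: frozenset[str] = ENGLISH_STOP_WORDS

_WORD_RE = re.compile(r"[a-z0-9']+")
_SENTENCE_RE = re.compile(r"[.!?]+")


def word_tokens(text: str) -> list[str]:
    """Lowercased alphanumeric tokens (apostrophes kept: "don't" is one token)."""
    return _WORD_RE.findall(text.lower())


def whitespace_count(text: str) -> int:
    """Word count as whitespace-delimited tokens after collapsing runs."""
    return len(text.split())


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation; empty segments dropped."""
    return [s.strip() for s in _SENTENCE_RE.split(text) if s.strip()]
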