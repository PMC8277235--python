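"""Shared lexical machinery: tokenization, sentence splitting, keyword matching.

All offsets are 0-based, end-exclusive, counted in Unicode code points
(the BRAT convention). Tokens are maximal runs of word characters;
hyphens and apostrophes inside a token are literal, so "one-sided" is a
single token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

_TOKEN_RE = re.compile(r"\w+(?:[-']\w+)*", re.UNICODE)

#: Abbreviations that must not terminate a sentence despite a trailing period.
ABBREVIATIONS = frozenset(
    {"e.g", "i.e", "etc", "dr", "fig", "al", "vs", "approx", "cf", "no", "spp"}
)

_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into word tokens with character spans."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def split_sentences(text: str) -> list[tuple[str, tuple[int, int]]]:
    """Rule-based sentence splitter for encyclopedic prose.

    Splits on runs of ``.!?`` followed by whitespace or end of text, with
    an abbreviation stop-list. Returned intervals tile the text in order
    (leading/trailing whitespace is trimmed from each sentence span);
    every character belongs to at most one sentence.
    """
    if not text.strip():
        return []
    boundaries: list[int] = []
    abbrev_re = re.compile(r"(\w+(?:\.\w+)*)$")
    for m in _SENT_BOUNDARY_RE.finditer(text):
        tail = abbrev_re.search(text[: m.start()][-12:])
        if tail and tail.group(1).lower() in ABBREVIATIONS:
            continue
        boundaries.append(m.end())
    if not boundaries or boundaries[-1] < len(text):
        boundaries.append(len(text))
    sentences: list[tuple[str, tuple[int, int]]] = []
    prev = 0
    for b in boundaries:
        chunk = text[prev:b]
        stripped = chunk.strip()
        if stripped:
            start = prev + len(chunk) - len(chunk.lstrip())
            sentences.append((stripped, (start, start + len(stripped))))
        prev = b
    return sentences


class KeywordMatcher:
    """Case-insensitive, whole-word, longest-match-first keyword matcher.

    Terms are normalized to lowercase token tuples at insertion. Matching
    walks the token sequence of the input; at each position the longest
    matching term wins and consumes its tokens, so matches never overlap.
    """

    def __init__(self) -> None:
        self._terms: dict[tuple[str, ...], object] = {}
        self._max_len = 0

    def add(self, term: str, payload: object) -> None:
        key = tuple(t.text.lower() for t in tokenize(term))
        if not key:
            raise ValueError(f"term normalizes to nothing: {term!r}")
        self._terms[key] = payload
        self._max_len = max(self._max_len, len(key))

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term: str) -> bool:
        return tuple(t.text.lower() for t in tokenize(term)) in self._terms

    def payload(self, term: str) -> object:
        return self._terms[tuple(t.text.lower() for t in tokenize(term))]

    def find(
        self, text: str, tokens: Sequence[Token] | None = None
    ) -> list[tuple[int, int, object]]:
        """Return non-overlapping matches as (start, end, payload) triples."""
        if tokens is None:
            tokens = tokenize(text)
        lowered = [t.text.lower() for t in tokens]
        out: list[tuple[int, int, object]] = []
        i = 0
        n = len(tokens)
        while i < n:
            hit = None
            for length in range(min(self._max_len, n - i), 0, -1):
                key = tuple(lowered[i : i + length])
                if key in self._terms:
                    hit = (length, self._terms[key])
                    break
            if hit is None:
                i += 1
            else:
                length, payload = hit
                out.append((tokens[i].start, tokens[i + length - 1].end, payload))
                i += length
        return out


def build_matcher(terms: Iterable[tuple[str, object]]) -> KeywordMatcher:
    m = KeywordMatcher()
    for term, payload in terms:
        m.add(term, payload)
    return m
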