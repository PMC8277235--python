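"""Dictionary-based phenotype concept recognition.

The default engine is a whole-token, case-insensitive, longest-match-first
dictionary matcher over a term -> (SNOMED code, preferred label) lexicon;
an adapter ingests span/code records from any external recognizer so the
choice of engine stays orthogonal to the rest of the pipeline. No
abbreviation expansion or word-sense disambiguation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from ._text import KeywordMatcher, build_matcher, tokenize
from .model import PhenoSSUError, PhenotypeConcept

logger = logging.getLogger(__name__)


class LexiconError(PhenoSSUError):
    """Lexicon file malformed or contains conflicting entries."""


@dataclass
class PhenotypeLexicon:
    """Surface term -> (snomed_code, preferred_label), with case-folded
    token-sequence normalization; conflicting duplicates are rejected at load."""

    entries: dict[str, tuple[str, str]]
    matcher: KeywordMatcher

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, term: str) -> tuple[str, str] | None:
        return self.entries.get(_normalize_term(term))


def _normalize_term(term: str) -> str:
    return " ".join(t.text.lower() for t in tokenize(term))


def build_lexicon(rows: Iterable[tuple[str, str, str]]) -> PhenotypeLexicon:
    entries: dict[str, tuple[str, str]] = {}
    for term, code, label in rows:
        key = _normalize_term(term)
        if not key:
            raise LexiconError(f"term {term!r} normalizes to nothing")
        if key in entries and entries[key][0] != code:
            raise LexiconError(
                f"conflicting codes for term {term!r}: "
                f"{entries[key][0]} vs {code}"
            )
        entries[key] = (code, label)
    matcher = build_matcher((term, term) for term in entries)
    return PhenotypeLexicon(entries=entries, matcher=matcher)


def load_lexicon(path: str | Path) -> PhenotypeLexicon:
    """Load a 2- or 3-column TSV (term, code[, label]) lexicon."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise LexiconError(f"{path}:{lineno}: expected >=2 columns")
        term, code = parts[0], parts[1]
        label = parts[2] if len(parts) > 2 else term
        rows.append((term, code, label))
    return build_lexicon(rows)


def default_lexicon() -> PhenotypeLexicon:
    """The shipped mini phenotype lexicon (a few dozen common infectious-disease
    phenotypes with SNOMED codes)."""
    with resources.as_file(
        resources.files("phenossu.data").joinpath("mini_lexicon.tsv")
    ) as p:
        return load_lexicon(p)


def default_site_lexicon() -> dict[str, tuple[str, str]]:
    """Finding-site surface -> (body-structure code, label) mapping."""
    mapping = {}
    with resources.files("phenossu.data").joinpath("site_lexicon.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            term, code, label = line.rstrip("\n").split("\t")[:3]
            mapping[term.lower()] = (code, label)
    return mapping


def recognize(text: str, lexicon: PhenotypeLexicon) -> list[PhenotypeConcept]:
    """All phenotype mentions in ``text``: case-insensitive, whole-token,
    longest-match-first, non-overlapping; each carries its SNOMED code."""
    concepts = []
    for start, end, term_key in lexicon.matcher.find(text):
        code, label = lexicon.entries[str(term_key)]
        concepts.append(
            PhenotypeConcept(
                surface_form=text[start:end],
                span=(start, end),
                snomed_code=code,
                preferred_label=label,
            )
        )
    return concepts


def ingest_external_spans(
    records: Sequence[tuple[tuple[int, int], str]],
    doc_text: str,
    lexicon: PhenotypeLexicon | None = None,
) -> list[PhenotypeConcept]:
    """Adapter for MetaMap-style external recognizer output: a list of
    ((start, end), code) records over ``doc_text``. Out-of-bound or empty
    spans are dropped individually with a warning; if every record is
    invalid, that is an input error."""
    concepts = []
    for span, code in records:
        start, end = span
        if not (0 <= start < end <= len(doc_text)):
            logger.warning(
                "dropping external span %s (document length %d)", span, len(doc_text)
            )
            continue
        surface = doc_text[start:end]
        label = ""
        if lexicon is not None:
            hit = lexicon.lookup(surface)
            if hit is not None:
                label = hit[1]
        concepts.append(
            PhenotypeConcept(
                surface_form=surface, span=(start, end),
                snomed_code=code, preferred_label=label,
            )
        )
    if records and not concepts:
        raise PhenoSSUError("all external span records were invalid")
    return concepts
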