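"""Co-occurrence attribute mining.

Candidate attributes for the phenotype model are found by counting, per
attribute, the sentences in which at least one trigger term of any of its
values co-occurs with at least one phenotype mention; attributes that
co-occur with phenotypes in at least ``min_sentences`` sentences across the
whole corpus (default 2) survive the filter. Co-occurrence requires nothing
beyond same-sentence membership. The returned candidates are intended for
human review, not a final schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from ._text import build_matcher, split_sentences, tokenize
from .model import AttributeSchema
from .recognition import PhenotypeLexicon

__all__ = [
    "CooccurrenceTable",
    "split_sentences",
    "find_trigger_mentions",
    "build_cooccurrence_table",
    "filter_candidate_attributes",
]


@dataclass
class CooccurrenceTable:
    """Per attribute: the set of sentence ids in which one of its value
    triggers co-occurred with a phenotype mention (plus a per-value
    breakdown for reporting)."""

    sentences: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    per_value: dict[tuple[str, str], set[tuple[str, int]]] = field(default_factory=dict)

    def count(self, attribute: str) -> int:
        return len(self.sentences.get(attribute, ()))

    @property
    def attributes(self) -> list[str]:
        return sorted(self.sentences)


def _attribute_matcher(schema: AttributeSchema):
    pairs = []
    for attr in schema:
        for value in attr.nondefault_values:
            for term in value.trigger_terms:
                pairs.append((term, (attr.name, value.label)))
    return build_matcher(pairs)


def find_trigger_mentions(
    sentence: str, schema: AttributeSchema
) -> list[tuple[str, str, tuple[int, int]]]:
    """All attribute-value trigger mentions in one sentence, as
    (attribute, value, span) triples. Matching is case-insensitive,
    whole-word, longest-match-first; matches never overlap."""
    matcher = _attribute_matcher(schema)
    return [
        (payload[0], payload[1], (start, end))
        for start, end, payload in matcher.find(sentence)
    ]


def build_cooccurrence_table(
    corpus: Iterable[tuple[str, str]],
    lexicon: PhenotypeLexicon,
    schema: AttributeSchema,
) -> CooccurrenceTable:
    """Count sentence-level phenotype/trigger co-occurrences over a corpus of
    (doc_id, text) pairs. A sentence contributes to attribute ``a`` iff it
    contains at least one phenotype mention and at least one trigger of any
    value of ``a``."""
    table = CooccurrenceTable()
    trig_matcher = _attribute_matcher(schema)
    for doc_id, text in corpus:
        for sent_idx, (sentence, _interval) in enumerate(split_sentences(text)):
            tokens = tokenize(sentence)
            if not lexicon.matcher.find(sentence, tokens):
                continue
            sid = (doc_id, sent_idx)
            for _s, _e, (attr_name, value_label) in trig_matcher.find(sentence, tokens):
                table.sentences.setdefault(attr_name, set()).add(sid)
                table.per_value.setdefault((attr_name, value_label), set()).add(sid)
    return table


def filter_candidate_attributes(
    table: CooccurrenceTable, min_sentences: int = 2
) -> list[str]:
    """Attributes co-occurring with phenotypes in >= ``min_sentences``
    sentences, sorted by descending count then name."""
    if min_sentences < 1:
        raise ValueError("min_sentences must be >= 1")
    kept = [a for a in table.sentences if table.count(a) >= min_sentences]
    return sorted(kept, key=lambda a: (-table.count(a), a))


def cooccurrence_report(table: CooccurrenceTable) -> str:
    """TSV report: attribute, value, sentence count (plus attribute totals)."""
    lines = ["attribute\tvalue\tsentences"]
    for attr in sorted(table.sentences, key=lambda a: (-table.count(a), a)):
        lines.append(f"{attr}\t*\t{table.count(attr)}")
        values = sorted(
            (v for (a, v) in table.per_value if a == attr),
            key=lambda v: (-len(table.per_value[(attr, v)]), v),
        )
        for v in values:
            lines.append(f"{attr}\t{v}\t{len(table.per_value[(attr, v)])}")
    return "\n".join(lines) + "\n"
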