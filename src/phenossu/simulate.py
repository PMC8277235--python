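"""Seeded generator of guideline-like corpora with exact gold annotations.

Sentences are assembled from a fixed slot template (frequency cue, assertion
cue, manifestation cues, the phenotype term, spatial cues, an optional
finding-site phrase), so the gold standoff annotation is exact by
construction: an attribute is non-default in the gold iff its trigger was
planted non-ambiguously. A trigger-ambiguity knob plants triggers whose
attribute does NOT apply, which is what makes attribute prediction hard;
the unambiguous regime (ambiguity 0) is linearly separable by design.

All randomness flows through one ``random.Random(seed)`` stream (integer
draws only), so corpora are byte-identical across platforms for a fixed
config.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .brat import StandoffDocument, from_instances, merge_annotations, to_instances
from .model import (
    AttributeSchema,
    FindingSite,
    PhenoSSUInstance,
    PhenotypeConcept,
    default_schema,
    new_instance,
    set_attribute,
)
from .recognition import PhenotypeLexicon, default_lexicon, default_site_lexicon

#: Per-attribute probability that a sentence's phenotype carries a
#: non-default value; sums to ~1.3 non-default values per instance, with the
#: presence attributes (assertion, frequency) and severity/temporal pattern
#: the most prevalent, mirroring the skew typical of guideline prose.
DEFAULT_PREVALENCE: dict[str, float] = {
    "assertion": 0.25,
    "frequency": 0.30,
    "age_specificity": 0.15,
    "sex_specificity": 0.05,
    "severity_of_illness_specificity": 0.05,
    "temporal_pattern": 0.15,
    "severity": 0.15,
    "appearance_color": 0.05,
    "sensation": 0.05,
    "laterality": 0.05,
    "spatial_pattern": 0.03,
    "quadrant_pattern": 0.02,
}

_OPENERS = ("patients", "individuals", "some people")
_VERBS = ("develop", "experience", "show")

# slot position of each attribute relative to the phenotype term
_PREFIX_ATTRS = ("temporal_pattern", "severity", "appearance_color", "sensation")
_SUFFIX_ATTRS = ("laterality", "spatial_pattern", "quadrant_pattern")
_TAIL_ATTRS = (
    "age_specificity",
    "sex_specificity",
    "severity_of_illness_specificity",
)
_TAIL_PREP = {"age_specificity": "among", "sex_specificity": "among",
              "severity_of_illness_specificity": ""}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_documents: int = 20
    sentences_per_document: int = 10
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    ambiguity_rate: float = 0.0
    disagreement_rate: float = 0.1
    site_prevalence: float = 0.15

    def __post_init__(self) -> None:
        for name, p in {
            "ambiguity_rate": self.ambiguity_rate,
            "disagreement_rate": self.disagreement_rate,
            "site_prevalence": self.site_prevalence,
            **{f"prevalence[{k}]": v for k, v in self.prevalence.items()},
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def _pick_trigger(rng: random.Random, attr) -> tuple[str, str]:
    """(value_label, trigger_term) drawn uniformly over non-default values."""
    value = rng.choice(list(attr.nondefault_values))
    term = rng.choice(sorted(value.trigger_terms))
    return value.label, term


def _sentence(
    rng: random.Random,
    schema: AttributeSchema,
    lexicon: PhenotypeLexicon,
    site_lexicon: dict[str, tuple[str, str]],
    config: GeneratorConfig,
) -> tuple[str, tuple[int, int], dict[str, str], tuple[tuple[int, int], str] | None]:
    """Build one sentence. Returns (sentence_text, phenotype_char_span,
    gold non-default values, optional (site_char_span, site_surface))."""
    planted: dict[str, str] = {}

    def decide(attr_name: str) -> str | None:
        """Return a trigger term to plant for this attribute, updating the
        gold when the planting is non-ambiguous."""
        attr = schema.attribute(attr_name)
        if rng.random() < config.prevalence.get(attr_name, 0.0):
            label, term = _pick_trigger(rng, attr)
            planted[attr_name] = label
            return term
        if config.ambiguity_rate and rng.random() < config.ambiguity_rate:
            _label, term = _pick_trigger(rng, attr)  # trigger without the attribute
            return term
        return None

    words: list[str] = [rng.choice(_OPENERS)]
    freq = decide("frequency")
    if freq:
        words.append(freq)
    assertion = decide("assertion")
    words.append(assertion if assertion else "typically")
    words.append(rng.choice(_VERBS))
    for attr_name in _PREFIX_ATTRS:
        term = decide(attr_name)
        if term:
            words.append(term)

    pheno_term = rng.choice(sorted(lexicon.entries))
    pheno_start = len(" ".join(words)) + 1 if words else 0
    words.append(pheno_term)
    pheno_span = (pheno_start, pheno_start + len(pheno_term))

    for attr_name in _SUFFIX_ATTRS:
        term = decide(attr_name)
        if term:
            if attr_name == "quadrant_pattern":
                words.extend(["in", "the", term, "region"])
            else:
                words.append(term)

    site = None
    if rng.random() < config.site_prevalence:
        site_term = rng.choice(sorted(site_lexicon))
        words.extend(["from", "the"])
        site_start = len(" ".join(words)) + 1
        words.append(site_term)
        site = ((site_start, site_start + len(site_term)), site_term)

    for attr_name in _TAIL_ATTRS:
        term = decide(attr_name)
        if term:
            prep = _TAIL_PREP[attr_name]
            if prep:
                words.append(prep)
            words.append(term)

    text = " ".join(words) + "."
    return text, pheno_span, planted, site


def generate_corpus(
    config: GeneratorConfig,
    schema: AttributeSchema | None = None,
    lexicon: PhenotypeLexicon | None = None,
) -> list[tuple[str, StandoffDocument]]:
    """Generate (doc_text, gold StandoffDocument) pairs; one phenotype
    mention per sentence, byte-identical output for a fixed config."""
    schema = schema or default_schema()
    lexicon = lexicon or default_lexicon()
    site_lex = default_site_lexicon()
    rng = random.Random(config.seed)
    corpus = []
    for d in range(config.n_documents):
        doc_id = f"synth{d:03d}"
        offset = 0
        parts: list[str] = []
        instances: list[PhenoSSUInstance] = []
        for _ in range(config.sentences_per_document):
            sent, pheno_span, planted, site = _sentence(
                rng, schema, lexicon, site_lex, config
            )
            start, end = pheno_span[0] + offset, pheno_span[1] + offset
            concept = PhenotypeConcept(
                surface_form=sent[pheno_span[0] : pheno_span[1]], span=(start, end)
            )
            inst = new_instance(concept, schema)
            for name, label in planted.items():
                inst = set_attribute(inst, schema, name, label)
            if site is not None:
                (s0, s1), surface = site
                code, label = site_lex.get(surface, ("", ""))
                inst = replace(
                    inst,
                    finding_sites=(
                        FindingSite(
                            surface_form=surface, span=(s0 + offset, s1 + offset),
                            snomed_code=code, preferred_label=label,
                        ),
                    ),
                )
            instances.append(inst)
            parts.append(sent)
            offset += len(sent) + 1
        text = " ".join(parts)
        corpus.append((text, from_instances(doc_id, text, instances, schema)))
    return corpus


def planted_nondefault_count(
    corpus: Sequence[tuple[str, StandoffDocument]], schema: AttributeSchema
) -> int:
    """Ground-truth count of non-default attribute values across a corpus."""
    names = set(schema.names)
    return sum(
        sum(1 for a in gold.attributes if a.name in names) for _text, gold in corpus
    )


def generate_annotator_pair(
    gold_docs: Sequence[tuple[str, StandoffDocument]],
    disagreement_rate: float,
    seed: int,
    schema: AttributeSchema | None = None,
    span_shift_prob: float = 0.3,
) -> tuple[list[tuple[str, StandoffDocument]], list[tuple[str, StandoffDocument]]]:
    """Simulate a second annotation pass: annotator A is the gold; annotator
    B perturbs each instance independently with the given probability, either
    flipping one attribute to a different member of its value set or shifting
    the phenotype span by one character."""
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must be in [0, 1]")
    schema = schema or default_schema()
    rng = random.Random(seed)
    docs_a, docs_b = [], []
    for text, gold in gold_docs:
        perturbed = []
        for inst in to_instances(gold, schema):
            if rng.random() < disagreement_rate:
                if rng.random() < span_shift_prob:
                    start, end = inst.concept.span
                    new_span = (start + 1, end) if end - start > 1 else (start, end + 1)
                    if new_span[1] > len(text):
                        new_span = (start + 1, end)
                    concept = PhenotypeConcept(
                        surface_form=text[new_span[0] : new_span[1]], span=new_span
                    )
                    inst = replace(inst, concept=concept)
                else:
                    attr = rng.choice(list(schema.attributes))
                    current = inst.values[attr.name]
                    others = [l for l in attr.labels if l != current]
                    inst = set_attribute(inst, schema, attr.name, rng.choice(others))
            perturbed.append(inst)
        docs_a.append((text, gold))
        docs_b.append((text, from_instances(gold.doc_id, text, perturbed, schema)))
    return docs_a, docs_b


def observed_disagreement(
    docs_a: Sequence[tuple[str, StandoffDocument]],
    docs_b: Sequence[tuple[str, StandoffDocument]],
    schema: AttributeSchema | None = None,
) -> float:
    """Fraction of annotator-A instances with no agreeing partner after the
    merge — the empirical counterpart of the generator's disagreement rate."""
    schema = schema or default_schema()
    n_gold = 0
    n_agree = 0
    for (text, da), (_tb, db) in zip(docs_a, docs_b):
        n_gold += sum(1 for e in da.entities if e.type == "Phenotype")
        merged = merge_annotations(da, db, schema)
        n_agree += sum(
            1 for inst in to_instances(merged, schema) if inst.agreement == "agree"
        )
    if n_gold == 0:
        raise ValueError("no gold instances")
    return 1.0 - n_agree / n_gold


#: canonical category names for the expressiveness generator, ordered from
#: the weakest profile that still represents the instance precisely
EXPRESSIVENESS_CATEGORIES = (
    "concept_only_precise",
    "fhir_precise_only",
    "cem_precise_only",
    "phenossu_precise_only",
    "partial",
)


def generate_expressiveness_corpus(
    counts: Mapping[str, int], schema: AttributeSchema | None = None
) -> list[PhenoSSUInstance]:
    """Emit gold instances in fixed representability strata.

    - ``concept_only_precise``: full, no non-default attributes;
    - ``fhir_precise_only``: full, severity non-default (smallest profile
      that captures it has severity);
    - ``cem_precise_only``: full, assertion non-default (needs assertion);
    - ``phenossu_precise_only``: full, temporal pattern non-default (only
      the full model has it);
    - ``partial``: the annotation itself missed part of the semantics.
    """
    schema = schema or default_schema()
    unknown = set(counts) - set(EXPRESSIVENESS_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown expressiveness categories: {sorted(unknown)}")
    recipes = {
        "concept_only_precise": {},
        "fhir_precise_only": {"severity": "severe"},
        "cem_precise_only": {"assertion": "possible"},
        "phenossu_precise_only": {"temporal_pattern": "acute"},
        "partial": {},
    }
    out: list[PhenoSSUInstance] = []
    for category in EXPRESSIVENESS_CATEGORIES:
        n = int(counts.get(category, 0))
        if n < 0:
            raise ValueError(f"negative count for {category}")
        concept = PhenotypeConcept(surface_form="fever", span=(0, 5))
        proto = new_instance(concept, schema)
        for attr, value in recipes[category].items():
            proto = set_attribute(proto, schema, attr, value)
        if category == "partial":
            proto = replace(proto, equal_to_original="partial")
        out.extend([proto] * n)
    return out
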