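"""Core domain types for the PhenoSSU entity-attribute-value phenotype model.

A PhenoSSU instance couples one phenotype concept with a fixed, schema-defined
set of attributes (the shipped default has 12, grouped into presence /
manifestation / spatial categories), each drawn from a closed, SNOMED-coded
value set. Finding sites are separate entities linked to the phenotype, and
concept normalization prefers a precoordinated SNOMED concept when one exists
for the (phenotype, site) pair, falling back to a postcoordination expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

AGREE = "agree"
DISAGREE = "disagree"
FULL = "full"
PARTIAL = "partial"

CATEGORIES = ("presence", "manifestation", "spatial")


class PhenoSSUError(Exception):
    """Base class for package errors."""


class SchemaError(PhenoSSUError):
    """Schema config is malformed or violates a schema invariant."""


class ClosedVocabularyError(PhenoSSUError):
    """An attribute value outside the attribute's closed value set."""


class NormalizationError(PhenoSSUError):
    """A phenotype surface form could not be resolved to a SNOMED code."""

    def __init__(self, surface_form: str):
        super().__init__(f"cannot normalize phenotype: {surface_form!r}")
        self.surface_form = surface_form


@dataclass(frozen=True)
class AttributeValueDef:
    """One admissible value of an attribute: a SNOMED qualifier concept plus
    the surface trigger terms that signal it in text."""

    code: str
    label: str
    trigger_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.code:
            raise SchemaError(f"value {self.label!r} has an empty code")


@dataclass(frozen=True)
class AttributeDefinition:
    code: str
    name: str
    category: str
    value_set: tuple[AttributeValueDef, ...]
    default_value: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"attribute {self.name!r}: unknown category {self.category!r}"
            )
        if not self.value_set:
            raise SchemaError(f"attribute {self.name!r}: empty value set")
        labels = [v.label for v in self.value_set]
        if len(set(labels)) != len(labels):
            raise SchemaError(f"attribute {self.name!r}: duplicate value labels")
        if self.default_value not in set(labels):
            raise SchemaError(
                f"attribute {self.name!r}: default {self.default_value!r} "
                "is not in the value set"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(v.label for v in self.value_set)

    def value(self, label: str) -> AttributeValueDef:
        for v in self.value_set:
            if v.label == label:
                return v
        raise ClosedVocabularyError(
            f"{label!r} is not a value of attribute {self.name!r} "
            f"(value set: {list(self.labels)})"
        )

    @property
    def nondefault_values(self) -> tuple[AttributeValueDef, ...]:
        return tuple(v for v in self.value_set if v.label != self.default_value)


@dataclass(frozen=True)
class AttributeSchema:
    attributes: tuple[AttributeDefinition, ...]
    version: str = "0"

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate attribute names: {dupes}")

    def __iter__(self):
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def attribute(self, name: str) -> AttributeDefinition:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(f"no attribute named {name!r} in schema")

    def by_category(self, category: str) -> tuple[AttributeDefinition, ...]:
        return tuple(a for a in self.attributes if a.category == category)

    def defaults(self) -> dict[str, str]:
        return {a.name: a.default_value for a in self.attributes}


def _spans_ok(span: tuple[int, int]) -> bool:
    start, end = span
    return 0 <= start < end


@dataclass(frozen=True)
class PhenotypeConcept:
    surface_form: str
    span: tuple[int, int]
    snomed_code: str = ""
    preferred_label: str = ""

    def __post_init__(self) -> None:
        if not _spans_ok(self.span):
            raise ValueError(f"invalid span {self.span} for {self.surface_form!r}")


@dataclass(frozen=True)
class FindingSite:
    surface_form: str
    span: tuple[int, int]
    snomed_code: str = ""
    preferred_label: str = ""

    def __post_init__(self) -> None:
        if not _spans_ok(self.span):
            raise ValueError(f"invalid span {self.span} for {self.surface_form!r}")


@dataclass(frozen=True)
class NormalizedExpression:
    """A SNOMED rendering of a phenotype, one of three kinds:

    - ``precoordinated``: a single existing concept covers phenotype + site
      (bleeding + nose -> epistaxis);
    - ``postcoordinated``: phenotype and site codes combined because no
      single concept exists;
    - ``concept_only``: no finding site involved.
    """

    kind: str
    phenotype_code: str
    site_codes: tuple[str, ...] = ()
    display: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("precoordinated", "postcoordinated", "concept_only"):
            raise ValueError(f"unknown normalization kind {self.kind!r}")
        if self.kind == "postcoordinated" and not self.site_codes:
            raise ValueError("postcoordinated expression requires site codes")
        if self.kind in ("precoordinated", "concept_only") and self.site_codes:
            raise ValueError(f"{self.kind} expression must not carry site codes")


@dataclass(frozen=True)
class PhenoSSUInstance:
    concept: PhenotypeConcept
    values: Mapping[str, str]
    finding_sites: tuple[FindingSite, ...] = ()
    normalized: NormalizedExpression | None = None
    agreement: str = AGREE
    equal_to_original: str = FULL
    sentence_ref: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        if self.agreement not in (AGREE, DISAGREE):
            raise ValueError(f"agreement must be agree/disagree, got {self.agreement!r}")
        if self.equal_to_original not in (FULL, PARTIAL):
            raise ValueError(
                f"equal_to_original must be full/partial, got {self.equal_to_original!r}"
            )
        object.__setattr__(self, "values", dict(self.values))

    def value(self, attribute: str) -> str:
        return self.values[attribute]

    def nondefault_values(self, schema: AttributeSchema) -> dict[str, str]:
        return {
            a.name: self.values[a.name]
            for a in schema
            if self.values[a.name] != a.default_value
        }

    def signature(self) -> tuple:
        """Span + attribute assignment; the unit of annotator consistency."""
        return (self.concept.span, tuple(sorted(self.values.items())))


@dataclass
class PhenotypeKnowledgeGraph:
    disease_name: str
    source_doc: str
    instances: list[PhenoSSUInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        for inst in self.instances:
            if inst.sentence_ref is not None and inst.sentence_ref[0] != self.source_doc:
                raise ValueError(
                    f"instance sentence_ref {inst.sentence_ref} does not point "
                    f"into source document {self.source_doc!r}"
                )


# ---------------------------------------------------------------------------
# Schema loading
# ---------------------------------------------------------------------------

def _parse_schema_mapping(raw: Mapping) -> AttributeSchema:
    if not isinstance(raw, Mapping) or "attributes" not in raw:
        raise SchemaError("schema config must be a mapping with an 'attributes' list")
    attrs = []
    for entry in raw["attributes"]:
        name = entry.get("name", "<unnamed>")
        try:
            for key in ("name", "code", "category", "default", "values"):
                if key not in entry:
                    raise SchemaError(f"attribute {name!r}: missing field {key!r}")
            if not entry["values"]:
                raise SchemaError(f"attribute {name!r}: empty value set")
            values = []
            for v in entry["values"]:
                values.append(
                    AttributeValueDef(
                        code=str(v["code"]),
                        label=str(v["label"]),
                        trigger_terms=frozenset(v.get("triggers", ())),
                    )
                )
            default = str(entry["default"])
            if default not in {v.label for v in values}:
                if default not in ("none", "present"):
                    raise SchemaError(
                        f"attribute {name!r}: default {default!r} is not in "
                        "the value set"
                    )
                # "none"/"present" defaults are schema-level sentinels, not
                # SNOMED annotations: synthesize their value entry
                values.insert(
                    0, AttributeValueDef(code="__default__", label=default)
                )
            attrs.append(
                AttributeDefinition(
                    code=str(entry["code"]),
                    name=str(entry["name"]),
                    category=str(entry["category"]),
                    value_set=tuple(values),
                    default_value=default,
                )
            )
        except SchemaError:
            raise
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"attribute {name!r}: malformed entry ({exc})") from exc
    return AttributeSchema(attributes=tuple(attrs), version=str(raw.get("version", "0")))


def load_schema(config_path: str | Path) -> AttributeSchema:
    """Load and validate an attribute schema from a YAML/JSON config file.

    Rejects duplicate attribute names, defaults outside the value set and
    empty value sets, naming the offending attribute in the error.
    """
    path = Path(config_path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SchemaError(f"cannot parse schema config {path}: {exc}") from exc
    return _parse_schema_mapping(raw)


def default_schema() -> AttributeSchema:
    """The shipped 12-attribute schema (5 presence, 4 manifestation, 3 spatial)."""
    with resources.files("phenossu.data").joinpath("default_schema.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return _parse_schema_mapping(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Instance construction and mutation
# ---------------------------------------------------------------------------

def new_instance(
    concept: PhenotypeConcept,
    schema: AttributeSchema,
    sentence_ref: tuple[str, int] | None = None,
) -> PhenoSSUInstance:
    """A fresh instance carries every attribute at its default: ``present``
    for assertion, ``none`` for the rest (under the shipped schema)."""
    return PhenoSSUInstance(
        concept=concept, values=schema.defaults(), sentence_ref=sentence_ref
    )


def set_attribute(
    instance: PhenoSSUInstance, schema: AttributeSchema, attribute: str, value: str
) -> PhenoSSUInstance:
    attr = schema.attribute(attribute)
    attr.value(value)  # raises ClosedVocabularyError if out of vocabulary
    values = dict(instance.values)
    values[attribute] = value
    return replace(instance, values=values)


# ---------------------------------------------------------------------------
# Concept normalization
# ---------------------------------------------------------------------------

def _display_pair(code: str, label: str) -> str:
    return f"{code}|{label}" if label else code


def normalize_concept(
    concept: PhenotypeConcept,
    sites: Iterable[FindingSite] = (),
    precoordination_table: Mapping[tuple[str, str], tuple[str, str]] | None = None,
) -> NormalizedExpression:
    """Normalize a phenotype with its finding sites to a SNOMED expression.

    If the (phenotype_code, site_code) pair is in the precoordination table
    the single mapped concept is used; otherwise sites produce a
    postcoordination expression, and a site-less phenotype stays
    concept-only. The table maps (phenotype_code, site_code) ->
    (combined_code, combined_label).
    """
    if not concept.snomed_code:
        raise NormalizationError(concept.surface_form)
    sites = tuple(sites)
    table = precoordination_table or {}
    if len(sites) == 1:
        key = (concept.snomed_code, sites[0].snomed_code)
        if key in table:
            code, label = table[key]
            return NormalizedExpression(
                kind="precoordinated",
                phenotype_code=code,
                display=_display_pair(code, label),
            )
    if sites:
        pheno = _display_pair(concept.snomed_code, concept.preferred_label)
        site_part = ", ".join(
            f'"{_display_pair(s.snomed_code, s.preferred_label)}"' for s in sites
        )
        return NormalizedExpression(
            kind="postcoordinated",
            phenotype_code=concept.snomed_code,
            site_codes=tuple(s.snomed_code for s in sites),
            display=f'"{pheno}": {site_part}',
        )
    return NormalizedExpression(
        kind="concept_only",
        phenotype_code=concept.snomed_code,
        display=_display_pair(concept.snomed_code, concept.preferred_label),
    )


def load_precoordination_table(
    path: str | Path,
) -> dict[tuple[str, str], tuple[str, str]]:
    """Read a 4-column TSV: phenotype_code, site_code, combined_code, label."""
    table: dict[tuple[str, str], tuple[str, str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise PhenoSSUError(
                f"{path}:{lineno}: expected 4 tab-separated columns, got {len(parts)}"
            )
        table[(parts[0], parts[1])] = (parts[2], parts[3])
    return table


def default_precoordination_table() -> dict[tuple[str, str], tuple[str, str]]:
    with resources.as_file(
        resources.files("phenossu.data").joinpath("precoordination.tsv")
    ) as p:
        return load_precoordination_table(p)


# ---------------------------------------------------------------------------
# Graph-level operations and serialization
# ---------------------------------------------------------------------------

def count_nondefault_values(
    graph: PhenotypeKnowledgeGraph, schema: AttributeSchema
) -> int:
    """Total attribute values across the graph that differ from the default."""
    return sum(len(inst.nondefault_values(schema)) for inst in graph.instances)


def _instance_to_dict(inst: PhenoSSUInstance) -> dict:
    d = {
        "concept": {
            "surface_form": inst.concept.surface_form,
            "span": list(inst.concept.span),
            "snomed_code": inst.concept.snomed_code,
            "preferred_label": inst.concept.preferred_label,
        },
        "values": dict(inst.values),
        "finding_sites": [
            {
                "surface_form": s.surface_form,
                "span": list(s.span),
                "snomed_code": s.snomed_code,
                "preferred_label": s.preferred_label,
            }
            for s in inst.finding_sites
        ],
        "agreement": inst.agreement,
        "equal_to_original": inst.equal_to_original,
        "sentence_ref": list(inst.sentence_ref) if inst.sentence_ref else None,
    }
    if inst.normalized is not None:
        d["normalized"] = {
            "kind": inst.normalized.kind,
            "phenotype_code": inst.normalized.phenotype_code,
            "site_codes": list(inst.normalized.site_codes),
            "display": inst.normalized.display,
        }
    return d


def _instance_from_dict(d: Mapping) -> PhenoSSUInstance:
    try:
        concept = PhenotypeConcept(
            surface_form=d["concept"]["surface_form"],
            span=tuple(d["concept"]["span"]),
            snomed_code=d["concept"].get("snomed_code", ""),
            preferred_label=d["concept"].get("preferred_label", ""),
        )
        sites = tuple(
            FindingSite(
                surface_form=s["surface_form"],
                span=tuple(s["span"]),
                snomed_code=s.get("snomed_code", ""),
                preferred_label=s.get("preferred_label", ""),
            )
            for s in d.get("finding_sites", ())
        )
        normalized = None
        if d.get("normalized"):
            n = d["normalized"]
            normalized = NormalizedExpression(
                kind=n["kind"],
                phenotype_code=n["phenotype_code"],
                site_codes=tuple(n.get("site_codes", ())),
                display=n.get("display", ""),
            )
        ref = d.get("sentence_ref")
        return PhenoSSUInstance(
            concept=concept,
            values=dict(d["values"]),
            finding_sites=sites,
            normalized=normalized,
            agreement=d.get("agreement", AGREE),
            equal_to_original=d.get("equal_to_original", FULL),
            sentence_ref=(ref[0], ref[1]) if ref else None,
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise PhenoSSUError(f"malformed instance payload: {exc}") from exc


def serialize_graph(graph: PhenotypeKnowledgeGraph) -> str:
    """JSON export with stable field names; inverse of :func:`deserialize_graph`."""
    payload = {
        "disease_name": graph.disease_name,
        "source_doc": graph.source_doc,
        "instances": [_instance_to_dict(i) for i in graph.instances],
    }
    return json.dumps(payload, ensure_ascii=False, indent=2, sort_keys=True)


def deserialize_graph(text: str) -> PhenotypeKnowledgeGraph:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PhenoSSUError(f"malformed graph payload: {exc}") from exc
    if not isinstance(payload, dict) or "instances" not in payload:
        raise PhenoSSUError("graph payload must be an object with an 'instances' list")
    return PhenotypeKnowledgeGraph(
        disease_name=payload.get("disease_name", ""),
        source_doc=payload.get("source_doc", ""),
        instances=[_instance_from_dict(d) for d in payload["instances"]],
    )


def to_rdf(graph: PhenotypeKnowledgeGraph):
    """Optional RDF triple export (requires rdflib).

    Emits disease --has_phenotype--> instance nodes with one attribute edge
    per non-default-agnostic value.
    """
    from rdflib import BNode, Graph, Literal, Namespace

    NS = Namespace("https://example.org/phenossu/")
    g = Graph()
    disease = NS[graph.disease_name.replace(" ", "_") or "disease"]
    for inst in graph.instances:
        node = BNode()
        g.add((disease, NS.has_phenotype, node))
        g.add((node, NS.surface_form, Literal(inst.concept.surface_form)))
        if inst.concept.snomed_code:
            g.add((node, NS.snomed_code, Literal(inst.concept.snomed_code)))
        for name, value in inst.values.items():
            g.add((node, NS[name], Literal(value)))
        for site in inst.finding_sites:
            g.add((node, NS.finding_site, Literal(site.snomed_code or site.surface_form)))
    return g
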