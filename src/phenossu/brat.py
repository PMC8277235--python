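"""Bit-exact reader/writer for BRAT standoff annotation.

Handles T (entity), A (attribute) and R (relation) records; other line types
(N, #, E, ...) are preserved as opaque records and re-emitted verbatim.
Spans are 0-based, end-exclusive, in Unicode code points; discontinuous
spans ("0 5;10 14") are parsed into multi-interval form, and matching uses
the full interval tuple.

Also provides BRAT config generation from an attribute schema, conversion
between standoff documents and PhenoSSU instances, and merging of two
independent annotation passes with the ``agreement`` virtual attribute
(two passes agree on an instance only when both the text spans and every
attribute value coincide).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .model import (
    AGREE,
    DISAGREE,
    AttributeSchema,
    FindingSite,
    PhenoSSUError,
    PhenoSSUInstance,
    PhenotypeConcept,
    new_instance,
    set_attribute,
)

PHENOTYPE = "Phenotype"
FINDING_SITE = "FindingSite"
LOCATE = "locate"
AGREEMENT_ATTR = "agreement"
EQUAL_ATTR = "equal_to_original"
class StandoffIntegrityError(PhenoSSUError):
    """A standoff record contradicts the document text or BRAT grammar."""


class StandoffReferenceError(PhenoSSUError):
    """An annotation references an id that does not exist."""


Span = tuple[tuple[int, int], ...]  # one or more (start, end) fragments


@dataclass(frozen=True)
class EntityAnnotation:
    id: str
    type: str
    span: Span
    text: str

    @property
    def start(self) -> int:
        return self.span[0][0]

    @property
    def end(self) -> int:
        return self.span[-1][1]


@dataclass(frozen=True)
class AttributeAnnotation:
    id: str
    name: str
    target: str
    value: str


@dataclass(frozen=True)
class RelationAnnotation:
    id: str
    type: str
    arg1: str
    arg2: str


@dataclass
class StandoffDocument:
    doc_id: str
    text: str
    entities: list[EntityAnnotation] = field(default_factory=list)
    attributes: list[AttributeAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)
    opaque: list[str] = field(default_factory=list)

    def entity(self, eid: str) -> EntityAnnotation:
        for e in self.entities:
            if e.id == eid:
                return e
        raise StandoffReferenceError(f"{self.doc_id}: no entity {eid!r}")

    def attributes_of(self, eid: str) -> list[AttributeAnnotation]:
        return [a for a in self.attributes if a.target == eid]

    def sites_of(self, eid: str) -> list[EntityAnnotation]:
        return [
            self.entity(r.arg2)
            for r in self.relations
            if r.type == LOCATE and r.arg1 == eid
        ]


def _extract_span_text(text: str, span: Span) -> str:
    return " ".join(text[s:e] for s, e in span)


def _parse_span(field_str: str) -> Span:
    frags = []
    for frag in field_str.split(";"):
        parts = frag.split()
        if len(parts) != 2:
            raise StandoffIntegrityError(f"bad span fragment {frag!r}")
        start, end = int(parts[0]), int(parts[1])
        if not 0 <= start < end:
            raise StandoffIntegrityError(f"bad span interval {frag!r}")
        frags.append((start, end))
    return tuple(frags)


_ID_RE = re.compile(r"([TAR])(\d+)$")


def parse_standoff(ann_content: str, doc_text: str, doc_id: str = "") -> StandoffDocument:
    """Parse a BRAT .ann payload against its document text.

    Entity texts are verified against the document substring at the span
    (integrity error naming the line on mismatch); attribute and relation
    references must resolve (reference error otherwise). Unknown line
    types are kept as opaque records.
    """
    doc = StandoffDocument(doc_id=doc_id, text=doc_text)
    seen_ids: set[str] = set()
    pending_refs: list[tuple[int, str, str]] = []
    for lineno, line in enumerate(ann_content.splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        aid = fields[0]
        if aid in seen_ids:
            raise StandoffIntegrityError(f"line {lineno}: duplicate id {aid!r}")
        kind = aid[0] if aid else ""
        try:
            if kind == "T":
                if len(fields) < 2:
                    raise StandoffIntegrityError(f"line {lineno}: truncated T record")
                header = fields[1]
                etype, _, span_str = header.partition(" ")
                span = _parse_span(span_str)
                covered = _extract_span_text(doc_text, span)
                stated = fields[2] if len(fields) > 2 else ""
                if stated and stated != covered:
                    raise StandoffIntegrityError(
                        f"line {lineno}: span/text mismatch for {aid}: "
                        f"annotation says {stated!r}, document has {covered!r}"
                    )
                doc.entities.append(
                    EntityAnnotation(id=aid, type=etype, span=span, text=covered)
                )
                seen_ids.add(aid)
            elif kind == "A":
                parts = fields[1].split()
                if len(parts) == 2:  # binary BRAT attribute: value implied "true"
                    name, target, value = parts[0], parts[1], "true"
                elif len(parts) == 3:
                    name, target, value = parts
                else:
                    raise StandoffIntegrityError(f"line {lineno}: malformed A record")
                doc.attributes.append(
                    AttributeAnnotation(id=aid, name=name, target=target, value=value)
                )
                pending_refs.append((lineno, aid, target))
                seen_ids.add(aid)
            elif kind == "R":
                m = re.match(r"(\S+) Arg1:(\S+) Arg2:(\S+)", fields[1])
                if not m:
                    raise StandoffIntegrityError(f"line {lineno}: malformed R record")
                doc.relations.append(
                    RelationAnnotation(
                        id=aid, type=m.group(1), arg1=m.group(2), arg2=m.group(3)
                    )
                )
                pending_refs.append((lineno, aid, m.group(2)))
                pending_refs.append((lineno, aid, m.group(3)))
                seen_ids.add(aid)
            else:
                doc.opaque.append(line)
        except ValueError as exc:
            raise StandoffIntegrityError(f"line {lineno}: {exc}") from exc
    entity_ids = {e.id for e in doc.entities}
    for lineno, aid, target in pending_refs:
        if target not in entity_ids:
            raise StandoffReferenceError(
                f"line {lineno}: {aid} references missing entity {target!r}"
            )
    return doc


def _numeric_id(aid: str) -> int:
    m = _ID_RE.match(aid)
    return int(m.group(2)) if m else 0


def write_standoff(doc: StandoffDocument) -> str:
    """Serialize in canonical order: T, A, R blocks, each by numeric id."""
    entity_ids = {e.id for e in doc.entities}
    for a in doc.attributes:
        if a.target not in entity_ids:
            raise StandoffReferenceError(f"{a.id} references missing entity {a.target!r}")
    for r in doc.relations:
        for arg in (r.arg1, r.arg2):
            if arg not in entity_ids:
                raise StandoffReferenceError(f"{r.id} references missing entity {arg!r}")
    lines = []
    for e in sorted(doc.entities, key=lambda e: _numeric_id(e.id)):
        span_str = ";".join(f"{s} {t}" for s, t in e.span)
        lines.append(f"{e.id}\t{e.type} {span_str}\t{e.text}")
    for a in sorted(doc.attributes, key=lambda a: _numeric_id(a.id)):
        lines.append(f"{a.id}\t{a.name} {a.target} {a.value}")
    for r in sorted(doc.relations, key=lambda r: _numeric_id(r.id)):
        lines.append(f"{r.id}\t{r.type} Arg1:{r.arg1} Arg2:{r.arg2}")
    lines.extend(doc.opaque)
    return "\n".join(lines) + ("\n" if lines else "")


def generate_brat_config(schema: AttributeSchema) -> tuple[str, str]:
    """Emit (annotation.conf, visual.conf) declaring the entity types, the
    locate relation, one closed value list per schema attribute, and the two
    virtual attributes (agreement, equal_to_original)."""
    ann = ["[entities]", PHENOTYPE, FINDING_SITE, "", "[relations]",
           f"{LOCATE}\tArg1:{PHENOTYPE}, Arg2:{FINDING_SITE}", "", "[events]", "",
           "[attributes]"]
    for attr in schema:
        values = "|".join(a.label for a in attr.nondefault_values)
        ann.append(f"{attr.name}\tArg:{PHENOTYPE}, Value:{values}")
    ann.append(f"{AGREEMENT_ATTR}\tArg:{PHENOTYPE}, Value:{AGREE}|{DISAGREE}")
    ann.append(f"{EQUAL_ATTR}\tArg:{PHENOTYPE}, Value:full|partial")
    vis = ["[labels]", f"{PHENOTYPE} | Pheno", f"{FINDING_SITE} | Site", "",
           "[drawing]",
           f"{PHENOTYPE}\tbgColor:#ffe680",
           f"{FINDING_SITE}\tbgColor:#a6d8ff"]
    return "\n".join(ann) + "\n", "\n".join(vis) + "\n"


def to_instances(
    doc: StandoffDocument,
    schema: AttributeSchema,
    site_lexicon: dict[str, tuple[str, str]] | None = None,
) -> list[PhenoSSUInstance]:
    """One PhenoSSU instance per Phenotype entity: locate relations populate
    the finding sites, A-lines override the schema defaults, anything unset
    stays at its default. ``site_lexicon`` (surface -> (code, label)) is used
    to normalize finding-site entities when available."""
    instances = []
    for ent in doc.entities:
        if ent.type != PHENOTYPE:
            continue
        concept = PhenotypeConcept(
            surface_form=ent.text, span=(ent.start, ent.end)
        )
        inst = new_instance(concept, schema, sentence_ref=None)
        agreement, equal = AGREE, "full"
        for a in doc.attributes_of(ent.id):
            if a.name == AGREEMENT_ATTR:
                agreement = a.value
            elif a.name == EQUAL_ATTR:
                equal = a.value
            else:
                inst = set_attribute(inst, schema, a.name, a.value)
        sites = []
        for se in doc.sites_of(ent.id):
            code, label = "", ""
            if site_lexicon:
                code, label = site_lexicon.get(se.text.lower(), ("", ""))
            sites.append(
                FindingSite(
                    surface_form=se.text, span=(se.start, se.end),
                    snomed_code=code, preferred_label=label,
                )
            )
        inst = replace(
            inst,
            finding_sites=tuple(sites),
            agreement=agreement,
            equal_to_original=equal,
            sentence_ref=(doc.doc_id, 0) if doc.doc_id else None,
        )
        instances.append(inst)
    return instances


def from_instances(
    doc_id: str, text: str, instances: list[PhenoSSUInstance], schema: AttributeSchema
) -> StandoffDocument:
    """Inverse of :func:`to_instances` (modulo id numbering): emit T lines for
    phenotypes and finding sites, A lines for non-default values and non-default
    virtual flags, and locate relations."""
    doc = StandoffDocument(doc_id=doc_id, text=text)
    t_counter = a_counter = r_counter = 0
    for inst in instances:
        t_counter += 1
        pid = f"T{t_counter}"
        start, end = inst.concept.span
        doc.entities.append(
            EntityAnnotation(
                id=pid, type=PHENOTYPE, span=((start, end),),
                text=text[start:end],
            )
        )
        for name, value in inst.nondefault_values(schema).items():
            a_counter += 1
            doc.attributes.append(
                AttributeAnnotation(id=f"A{a_counter}", name=name, target=pid, value=value)
            )
        if inst.agreement != AGREE:
            a_counter += 1
            doc.attributes.append(
                AttributeAnnotation(
                    id=f"A{a_counter}", name=AGREEMENT_ATTR, target=pid, value=inst.agreement
                )
            )
        if inst.equal_to_original != "full":
            a_counter += 1
            doc.attributes.append(
                AttributeAnnotation(
                    id=f"A{a_counter}", name=EQUAL_ATTR, target=pid,
                    value=inst.equal_to_original,
                )
            )
        for site in inst.finding_sites:
            t_counter += 1
            sid = f"T{t_counter}"
            s, e = site.span
            doc.entities.append(
                EntityAnnotation(id=sid, type=FINDING_SITE, span=((s, e),), text=text[s:e])
            )
            r_counter += 1
            doc.relations.append(
                RelationAnnotation(id=f"R{r_counter}", type=LOCATE, arg1=pid, arg2=sid)
            )
    return doc


def merge_annotations(
    doc_a: StandoffDocument, doc_b: StandoffDocument, schema: AttributeSchema
) -> StandoffDocument:
    """Merge two independent annotation passes over the same text.

    Instances are aligned by identical span; a pair is consistent only when
    spans AND every attribute value match, in which case a single instance
    with agreement=agree is kept. Any other instance (span unmatched, or
    same span with differing values) is kept and marked agreement=disagree.
    """
    if doc_a.text != doc_b.text:
        raise PhenoSSUError(
            "cannot merge annotations over different document texts "
            f"({doc_a.doc_id!r} vs {doc_b.doc_id!r})"
        )
    inst_a = to_instances(doc_a, schema)
    inst_b = to_instances(doc_b, schema)
    by_span_b: dict[tuple[int, int], list[PhenoSSUInstance]] = {}
    for inst in inst_b:
        by_span_b.setdefault(inst.concept.span, []).append(inst)
    merged: list[PhenoSSUInstance] = []
    matched_b: set[int] = set()
    for ia in inst_a:
        partner = None
        for ib in by_span_b.get(ia.concept.span, ()):
            if id(ib) not in matched_b and dict(ib.values) == dict(ia.values):
                partner = ib
                break
        if partner is not None:
            matched_b.add(id(partner))
            merged.append(replace(ia, agreement=AGREE))
        else:
            merged.append(replace(ia, agreement=DISAGREE))
    for ib in inst_b:
        if id(ib) not in matched_b:
            merged.append(replace(ib, agreement=DISAGREE))
    return from_instances(doc_a.doc_id or doc_b.doc_id, doc_a.text, merged, schema)
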