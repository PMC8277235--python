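"""Schema loading/validation, instance defaults, closed vocabulary,
concept normalization and graph serialization."""

import pytest
import yaml

from phenossu import (
    ClosedVocabularyError,
    FindingSite,
    NormalizationError,
    PhenoSSUError,
    PhenotypeConcept,
    PhenotypeKnowledgeGraph,
    SchemaError,
    count_nondefault_values,
    default_precoordination_table,
    default_schema,
    deserialize_graph,
    load_schema,
    new_instance,
    normalize_concept,
    serialize_graph,
    set_attribute,
    to_instances,
)
from phenossu.simulate import GeneratorConfig, generate_corpus


def _write_schema(tmp_path, payload):
    p = tmp_path / "schema.yaml"
    p.write_text(yaml.safe_dump(payload), encoding="utf-8")
    return p


class TestSchemaLoading:
    def test_default_schema_has_12_attributes_in_3_categories(self, schema):
        assert len(schema) == 12
        assert len(schema.by_category("presence")) == 5
        assert len(schema.by_category("manifestation")) == 4
        assert len(schema.by_category("spatial")) == 3

    def test_severity_value_set_is_mild_moderate_severe(self, schema):
        severity = schema.attribute("severity")
        assert set(severity.labels) == {"none", "mild", "moderate", "severe"}
        assert severity.default_value == "none"

    def test_mild_moderate_severe_config_accepted(self, tmp_path):
        payload = {
            "version": "t",
            "attributes": [
                {
                    "name": "severity",
                    "code": "272141005",
                    "category": "manifestation",
                    "default": "none",
                    "values": [
                        {"label": "mild", "code": "255604002"},
                        {"label": "moderate", "code": "6736007"},
                        {"label": "severe", "code": "24484000"},
                    ],
                }
            ],
        }
        schema = load_schema(_write_schema(tmp_path, payload))
        assert schema.attribute("severity").labels == ("none", "mild", "moderate", "severe")

    @pytest.mark.parametrize(
        "mutation, match",
        [
            (lambda a: a.update(default="catastrophic", values=a["values"] + [
                {"label": "catastrophic_typo", "code": "1"}]), "severity"),
            (lambda a: a.update(values=[]), "severity"),
            (lambda a: a.pop("category"), "severity"),
        ],
    )
    def test_malformed_config_names_offending_attribute(self, tmp_path, mutation, match):
        attr = {
            "name": "severity",
            "code": "272141005",
            "category": "manifestation",
            "default": "mild",
            "values": [{"label": "mild", "code": "255604002"}],
        }
        mutation(attr)
        payload = {"attributes": [attr]}
        with pytest.raises(SchemaError, match=match):
            load_schema(_write_schema(tmp_path, payload))

    def test_duplicate_attribute_names_rejected(self, tmp_path):
        attr = {
            "name": "severity",
            "code": "272141005",
            "category": "manifestation",
            "default": "none",
            "values": [{"label": "mild", "code": "255604002"}],
        }
        with pytest.raises(SchemaError, match="duplicate"):
            load_schema(_write_schema(tmp_path, {"attributes": [attr, dict(attr)]}))


FEVER = PhenotypeConcept(
    surface_form="fever", span=(0, 5), snomed_code="386661006", preferred_label="Fever"
)


class TestInstances:
    def test_fresh_instance_has_assertion_present_rest_none(self, schema):
        inst = new_instance(FEVER, schema)
        assert inst.values["assertion"] == "present"
        assert all(
            inst.values[a.name] == "none" for a in schema if a.name != "assertion"
        )
        assert inst.nondefault_values(schema) == {}
        assert inst.agreement == "agree"
        assert inst.equal_to_original == "full"

    def test_fresh_instances_are_deterministic(self, schema):
        a, b = new_instance(FEVER, schema), new_instance(FEVER, schema)
        assert dict(a.values) == dict(b.values)

    def test_set_attribute_single_mutation(self, schema):
        inst = set_attribute(new_instance(FEVER, schema), schema, "severity", "severe")
        assert inst.nondefault_values(schema) == {"severity": "severe"}
        assert inst.concept == FEVER

    def test_set_attribute_rejects_out_of_vocabulary_value(self, schema):
        with pytest.raises(ClosedVocabularyError):
            set_attribute(new_instance(FEVER, schema), schema, "severity", "catastrophic")

    def test_set_attribute_read_back(self, schema):
        inst = set_attribute(
            new_instance(FEVER, schema), schema, "temporal_pattern", "acute"
        )
        assert inst.value("temporal_pattern") == "acute"


class TestNormalization:
    def test_bleeding_from_nose_is_precoordinated_epistaxis(self):
        bleeding = PhenotypeConcept(
            surface_form="bleeding", span=(0, 8), snomed_code="131148009",
            preferred_label="Bleeding",
        )
        nose = FindingSite(
            surface_form="nose", span=(18, 22), snomed_code="45206002",
            preferred_label="Nasal structure",
        )
        expr = normalize_concept(bleeding, [nose], default_precoordination_table())
        assert expr.kind == "precoordinated"
        assert expr.display == "249366005|epistaxis"
        assert expr.site_codes == ()

    def test_rash_on_hand_is_postcoordinated(self):
        rash = PhenotypeConcept(
            surface_form="rash", span=(0, 4), snomed_code="271807003",
            preferred_label="Rash",
        )
        hand = FindingSite(
            surface_form="hands", span=(10, 15), snomed_code="33712006",
            preferred_label="Skin structure of hand",
        )
        expr = normalize_concept(rash, [hand], default_precoordination_table())
        assert expr.kind == "postcoordinated"
        assert expr.display == '"271807003|Rash": "33712006|Skin structure of hand"'
        assert expr.site_codes == ("33712006",)

    def test_siteless_concept_stays_concept_only(self):
        expr = normalize_concept(FEVER)
        assert expr.kind == "concept_only"
        assert expr.phenotype_code == "386661006"

    def test_unresolvable_phenotype_raises_with_surface_form(self):
        mystery = PhenotypeConcept(surface_form="glowing aura", span=(0, 12))
        with pytest.raises(NormalizationError, match="glowing aura"):
            normalize_concept(mystery)


class TestGraphCounting:
    def test_fresh_instances_count_zero(self, schema):
        graph = PhenotypeKnowledgeGraph(
            disease_name="flu", source_doc="d",
            instances=[new_instance(FEVER, schema) for _ in range(3)],
        )
        assert count_nondefault_values(graph, schema) == 0

    def test_two_set_attributes_count_two(self, schema):
        inst = set_attribute(new_instance(FEVER, schema), schema, "severity", "severe")
        inst = set_attribute(inst, schema, "frequency", "frequent")
        graph = PhenotypeKnowledgeGraph("flu", "d", [inst])
        assert count_nondefault_values(graph, schema) == 2

    def test_generator_planted_count_matches_graph_count(self, schema, small_corpus):
        planted = sum(
            sum(1 for a in gold.attributes if a.name in set(schema.names))
            for _t, gold in small_corpus
        )
        total = 0
        for _text, gold in small_corpus:
            graph = PhenotypeKnowledgeGraph(
                "synthetic", gold.doc_id, to_instances(gold, schema)
            )
            total += count_nondefault_values(graph, schema)
        assert total == planted


class TestSerialization:
    def _fixture_graph(self, schema):
        inst = set_attribute(new_instance(FEVER, schema), schema, "severity", "severe")
        inst = normalize_and_ref(inst, "doc1")
        return PhenotypeKnowledgeGraph("dengue", "doc1", [inst])

    def test_round_trip_identity(self, schema):
        graph = self._fixture_graph(schema)
        again = deserialize_graph(serialize_graph(graph))
        assert again.disease_name == graph.disease_name
        assert again.instances == graph.instances

    def test_empty_graph_round_trip(self):
        graph = PhenotypeKnowledgeGraph("x", "d", [])
        assert deserialize_graph(serialize_graph(graph)).instances == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generated_graph_round_trip(self, schema, seed):
        corpus = generate_corpus(
            GeneratorConfig(seed=seed, n_documents=1, sentences_per_document=6), schema
        )
        _text, gold = corpus[0]
        instances = to_instances(gold, schema)
        graph = PhenotypeKnowledgeGraph("synthetic", gold.doc_id, instances)
        again = deserialize_graph(serialize_graph(graph))
        assert again.instances == graph.instances

    def test_malformed_payload_raises(self):
        with pytest.raises(PhenoSSUError):
            deserialize_graph("{not json")
        with pytest.raises(PhenoSSUError):
            deserialize_graph('{"no_instances": true}')


def normalize_and_ref(inst, doc_id):
    from dataclasses import replace

    return replace(
        inst, sentence_ref=(doc_id, 0), normalized=normalize_concept(inst.concept)
    )
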