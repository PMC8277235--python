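# phenossu

Fine-grained phenotype information modeling for clinical-guideline text.

Structured disease knowledge bases typically reduce a guideline's "signs and
symptoms" section to a bare list of phenotype concepts. That loses most of
what the prose actually says: *"common symptoms include sudden onset of
fever"* tells you not just `fever`, but that it is **possible** rather than
confirmed, **frequent** in the population, and **acute** in onset. `phenossu`
is a toolkit for capturing, mining, extracting and evaluating that level of
detail. It is aimed at medical knowledge engineers and clinical-NLP
researchers building phenotype knowledge graphs from encyclopedic disease
descriptions.

## The model

Each phenotype mention is modeled as an entity–attribute–value unit:

```
PhenoSSU = (concept, a₁=v₁, …, a₁₂=v₁₂)
```

where the concept and all values are SNOMED-CT coded and every attribute aᵢ
has a *closed* value set with a fixed default (`present` for assertion,
`none` for everything else). The shipped schema has 12 attributes in three
categories:

| category | attributes |
|---|---|
| presence | assertion, frequency, age specificity, sex specificity, severity-of-illness specificity |
| manifestation | temporal pattern, severity, appearance color, sensation |
| spatial | laterality, spatial pattern, quadrant pattern |

Finding sites (body structures) are separate entities linked to the
phenotype by a `locate` relation, not attributes; normalization prefers a
precoordinated SNOMED concept when one exists for the (phenotype, site)
pair (bleeding + nose → `249366005|epistaxis`) and falls back to a
postcoordination expression otherwise (`"271807003|Rash": "33712006|Skin
structure of hand"`).

Around this core the package provides:

- **`phenossu.brat`** — bit-exact BRAT standoff (.ann) reading/writing,
  BRAT config generation from a schema, conversion to/from instances, and
  merging of two independent annotation passes (an instance pair agrees
  only when both spans *and* all attribute values coincide; everything else
  is flagged `agreement=disagree`).
- **`phenossu.mining`** — sentence-level co-occurrence mining of candidate
  attributes: an attribute survives if one of its value triggers shares at
  least 2 sentences with a phenotype mention across the corpus.
- **`phenossu.recognition`** — dictionary-based phenotype concept
  recognition (case-insensitive, whole-token, longest-match-first) plus an
  adapter for external recognizer output.
- **`phenossu.prediction`** — per-attribute SVM value classifiers over
  trigger-presence + signed token-distance features, with SMOTE-style
  minority oversampling and cross-validated grid search; a constant
  default-value baseline; and the end-to-end hybrid extractor.
- **`phenossu.metrics`** — overlap-based span F1, per-attribute weighted
  (balanced) accuracy and its average (AWA), instance-level Cohen kappa
  with raw agreement reported alongside, and the precise-representation
  rate.
- **`phenossu.expressiveness`** — comparison of information-model profiles
  (full 12-attribute model vs CEM-like vs FHIR-like vs concept-only) by the
  percentage of gold instances each represents without semantic loss.
- **`phenossu.simulate`** — a seeded generator of guideline-like corpora
  with exact gold annotations, so every stage is testable offline.

## Worked example

Train on a synthetic unambiguous corpus, then extract from the sentence
above:

```python
from phenossu import (GeneratorConfig, default_lexicon, default_schema,
                      extract_phenossu, generate_corpus, serialize_graph,
                      train_all_attributes)

schema = default_schema()
prevalence = {a.name: 0.5 for a in schema}
corpus = generate_corpus(GeneratorConfig(seed=11, n_documents=20,
                                         sentences_per_document=10,
                                         prevalence=prevalence), schema)
classifiers = train_all_attributes(corpus[:12], schema, seed=11)
graph = extract_phenossu("common symptoms include sudden onset of fever",
                         default_lexicon(), classifiers, schema,
                         doc_id="example", disease_name="influenza")
print(serialize_graph(graph))
```

prints one instance (abridged):

```json
{
  "concept": {"surface_form": "fever", "snomed_code": "386661006", "span": [40, 45]},
  "normalized": {"kind": "concept_only", "display": "386661006|Fever"},
  "values": {"assertion": "possible", "frequency": "frequent",
             "temporal_pattern": "acute", "severity": "none", "...": "none"}
}
```

i.e. the extractor recovered all three non-default details of the
description: the phenotype is *possible* ("include"), *frequent*
("common"), and *acute* in onset ("sudden onset"); every other attribute
stays at its default.

The same pipeline is available from the shell:

```bash
phenossu simulate --out corpus/ --seed 11 --n-documents 20
phenossu train    --corpus corpus/ --out models/ --seed 11
phenossu extract  --model models/ --text corpus/synth015.txt --out graph.json
phenossu evaluate --pred preds/ --gold corpus/
phenossu compare-models --gold corpus/
```

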