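# Methods

This note documents the models, procedures and numerical choices behind
`phenossu`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The information model

A phenotype mention is a unit `(concept, attribute→value map)` where the
attribute set is fixed by a schema and every value set is closed and
SNOMED-coded. Defaults — `present` for assertion, `none` for every other
attribute — are schema-level sentinels rather than SNOMED annotations: a
guideline sentence that says nothing about severity is *not* asserting
"severity: none" as clinical content, so defaults are never written to
annotation files and never counted as annotated values. The schema loader
only synthesizes sentinel entries for the labels `none` and `present`; any
other default missing from its value set is a config error.

The shipped 12-attribute schema (5 presence, 4 manifestation, 3 spatial) is
config-driven YAML. Attribute and value codes printed in the literature we
model (severity `272141005`, laterality `272741003`, severe `24484000`,
unilateral `66459002`, the severity set {mild, moderate, severe}) are used
as-is; the remaining codes and value sets are best-effort picks from the
SNOMED qualifier-value hierarchy, flagged as such in config comments. A
corrected schema drops in without code changes. Trigger lexicons ship with
the schema and are deliberately **disjoint across attributes**, which is
what makes the unambiguous synthetic regime (below) linearly separable.

Finding sites are linked entities, not attributes: the >39k body-structure
concepts cannot form a closed value list. Normalization is a three-way
decision: `(phenotype_code, site_code)` found in the user-supplied
precoordination table → single precoordinated concept; sites present but no
table entry → postcoordination expression; no sites → concept only.
Character offsets everywhere are 0-based, end-exclusive, in Unicode code
points (the BRAT convention); discontinuous BRAT spans are parsed and kept
as multi-interval spans.

## Annotation merging and agreement

Two annotation passes are aligned by *identical* span. A pair is consistent
only when the spans and every attribute value match; a same-span pair with
any differing value yields two instances both flagged `disagree`, and an
unmatched span is a disagreement on its own. Instance-level Cohen kappa
treats the union of span keys as items and each annotator's full attribute
assignment (or "missing") as the rating; `po = 1` gives kappa 1 by
convention. Because quoted agreement figures are often raw proportions, the
kappa result carries `observed_agreement`, `expected_agreement` and the
counts alongside the statistic, so either convention can be read off.

## Attribute mining

Candidate attributes are mined from sentence-level co-occurrence only: a
sentence contributes to attribute *a* iff it contains ≥1 phenotype mention
and ≥1 trigger of any value of *a*; attributes below the 2-sentence
threshold are dropped. No proximity constraint beyond same-sentence
membership is applied, and the returned candidate list is input to human
review — the subsequent manual curation of "truly related" attributes is a
human process and out of scope. Sentence splitting is rule-based
(`[.!?]` + whitespace with an abbreviation stop-list), which is adequate
for encyclopedic prose and keeps the pipeline dependency-light.

## Concept recognition

The default engine is a dictionary matcher: case-insensitive, whole-token,
longest-match-first, non-overlapping, with Unicode word boundaries and
literal in-token hyphens. Ontology-driven recognizers (MetaMap-class tools
built on licensed terminologies) are intentionally not bundled; the
`ingest_external_spans` adapter accepts any recognizer's `(span, code)`
output so the engine choice is orthogonal to the rest of the pipeline. No
abbreviation expansion or word-sense disambiguation is attempted.

## Attribute value prediction

For one attribute with trigger terms t₁…t_k, a phenotype's sentence context
is encoded as a 2k-vector: per trigger, a presence flag and the signed
token distance between the trigger occurrence nearest the phenotype and the
phenotype itself (negative = left). Distance is measured between the facing
tokens — in *"common symptoms include sudden onset of fever"*, "sudden
onset" sits 2 tokens left of "fever" (distance −2). Multiple occurrences
aggregate by nearest occurrence. The context window defaults to the whole
sentence (`window = 512` tokens, i.e. effectively unbounded); a tighter
window treats out-of-range triggers as absent.

Training data are heavily skewed toward the default class, so minority
classes are rebalanced to the majority count by SMOTE-style interpolation
between same-class nearest neighbours (k ≤ 5, uniform interpolation
coefficient, deterministic given the seed); a single-example class is
duplicated. One SVM per attribute is then fitted with stratified
cross-validated grid search over C ∈ {0.1, 1, 10} × kernel ∈ {linear, RBF}
(5 folds, reduced to the minority count when smaller; never below 2).
Degenerate single-class data yields a constant classifier with a warning.
An all-zero feature vector short-circuits to the default label, which
guarantees the invariant that removing every trigger forces the default
prediction. The baseline model predicts the default unconditionally.

Any object with `predict_value(features) → label` and `feature_names` can
replace a trained SVM in the extractor, which is the intended plug-in point
for alternative (e.g. neural) classifiers; none are bundled.

## Evaluation metrics

Span F1 counts a prediction as a true positive when it can be paired
one-to-one with an *overlapping* gold span. The pairing maximizes the
number of matched pairs (maximum-cardinality bipartite matching on the
positive-overlap graph) rather than greedily matching by largest overlap:
greedy matching can strand a matchable pair in crossing-overlap
configurations, whereas maximum matching makes the true-positive count
well-defined and lets the implementation be checked against an exhaustive
oracle. Zero-denominator conventions: precision, recall and F1 are 0 when
there are no true positives.

Weighted accuracy for one attribute is the mean per-class recall over the
classes present in the gold (balanced accuracy); classes absent from the
gold are excluded. This is chosen because it rewards getting *rare* values
right — a constant-default predictor on a gold set with k classes scores
exactly 1/k however skewed the distribution. AWA is the unweighted mean
over attributes. The metric is swappable: `weighted_accuracy` is a plain
function and `evaluate_extraction` takes the attribute list explicitly.

The precise-representation rate is the percentage (1 decimal) of instances
whose `equal_to_original` flag is `full`, i.e. whose structured form lost
no semantics of the original description.

## Expressiveness comparison

An information-model profile is an attribute subset; an instance is
precisely representable under a profile iff it is `full` and its
non-default attributes all lie in the subset. Representability is therefore
monotone in the subset ordering by construction, and the comparison table
inherits that monotonicity. Shipped profiles: the full 12-attribute model;
a CEM-like profile {assertion, severity, laterality} (CEM records
uncertainty, which guidelines use constantly); a FHIR-like profile
{severity, laterality}; and concept-only {}. The exact CEM-17/FHIR
inventories are EMR-oriented and partly unpublished in the source we model,
so the profiles are approximations and fully config-driven.

## Synthetic data

The generator assembles sentences from a fixed slot template (frequency
cue, assertion cue, manifestation cues, phenotype term, spatial cues,
optional "from the &lt;site&gt;" phrase, population cues), so gold standoff
annotations are exact by construction. It makes no attempt to mimic natural
prose style; what it emulates is the *alignment structure* of guideline
sentences — triggers co-occurring with phenotype mentions at controlled
prevalence — not their fluency, vocabulary breadth, or discourse. Passing
tests on this corpus therefore demonstrate correctness of the machinery
(span bookkeeping, feature encoding, training, metrics), not performance on
real clinical guidelines, where concept variation, nested mentions,
ambiguous triggers and cross-sentence context dominate the error budget.

Default per-attribute non-default prevalences are skewed the way guideline
corpora are (assertion 0.25, frequency 0.30, age specificity / severity /
temporal pattern 0.15, the rest 0.02–0.05; ~1.3 non-default values per
instance). The `ambiguity_rate` knob plants triggers whose attribute does
not apply, which is the single hardest feature of real text for this
feature encoding; 0 makes the task separable. The annotator-pair simulator
perturbs each instance with the configured probability (attribute flip, or
a one-character span shift 30% of the time), which drives the merge/kappa
tests. All randomness flows through one `random.Random(seed)` stream, so
corpora are byte-identical across platforms.

The stratified expressiveness generator emits instances by the weakest
profile that still captures them precisely (all-default; severity-bearing;
assertion-bearing; temporal-pattern-bearing; `partial`), which turns the
comparison table into closed-form arithmetic on the stratum counts.

## Experiment sizes and determinism

The parameter-recovery experiment uses 200 sentences (20 documents × 10),
ambiguity 0, uniform prevalence 0.5, and a 6:4 train/test split by
document. Uniform 0.5 is the recovery design, not the corpus-statistics
default: under the skewed defaults several attribute values are never
observed in 120 training sentences, and no classifier can recover a class
it has never seen — recovery is only well-posed when every value occurs.
With this design the trained classifiers reach held-out AWA ≥ 0.95 and
strictly dominate the constant-default baseline (the test suite and
acceptance script compute the actual numbers on every run).

Oracle-equivalence checks run the co-occurrence counter against a naive
regex recount and the span matcher against an exhaustive matching recursion
on 100 seeded random cases (corpora ≤ 8 sentences, span sets ≤ 20 spans).
Statistical checks (planted prevalence, disagreement calibration) use
~3-sigma binomial bands at n = 500–600. Everything that draws randomness
takes an explicit seed; grid search, oversampling and SVM fitting are
seeded, so identical corpora and seeds give identical models and
predictions.

## Known limitations

- The dictionary recognizer has no term variation (inflection, synonymy,
  abbreviation), so recall on real text is bounded by lexicon coverage.
- One classifier per attribute; cross-attribute interactions (e.g.
  assertion scope affecting severity) are not modeled.
- Trigger lexicons are starter sets, not a curated inventory; real corpora
  need per-corpus extension.
- The CEM/FHIR profiles are attribute-subset projections, not semantic
  re-annotations under those models' native structures.
- Sentence-level context only: attributes expressed in a neighbouring
  sentence are invisible to the feature encoding.
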