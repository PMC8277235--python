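"""Per-attribute value classification from a phenotype's sentence context.

The context of a phenotype is encoded, for every trigger term of the
attribute's value set, as a presence flag plus the signed token distance
from the trigger's nearest occurrence to the phenotype (negative = trigger
to the left). Severely imbalanced training sets (the default value
dominates) are rebalanced by synthetic minority oversampling before a
max-margin classifier is fitted with cross-validated grid search over
regularization strength and kernel. A constant default-value predictor
serves as the reference baseline, and the end-to-end hybrid extractor
first recognizes phenotype concepts and then predicts the values of every
schema attribute for each of them.

Any object exposing ``predict_value(features) -> label`` and a
``feature_names`` sequence satisfies the predictor contract, so alternative
classifiers (e.g. neural encoders) can be plugged into the extractor.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from ._text import split_sentences, tokenize
from .brat import StandoffDocument, to_instances
from .model import (
    AttributeDefinition,
    AttributeSchema,
    PhenoSSUError,
    PhenotypeKnowledgeGraph,
    normalize_concept,
    new_instance,
    set_attribute,
)
from .recognition import PhenotypeLexicon, recognize

logger = logging.getLogger(__name__)

#: token-distance clip used when no window is given: effectively "whole sentence"
WHOLE_SENTENCE = 512

DEFAULT_GRID: dict[str, list] = {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]}


def trigger_inventory(attribute: AttributeDefinition) -> list[tuple[str, str]]:
    """Deterministic (value_label, trigger_term) order defining the feature
    layout for one attribute."""
    inv = []
    for value in attribute.nondefault_values:
        for term in sorted(value.trigger_terms):
            inv.append((value.label, term))
    return inv


def encode_context(
    sentence_tokens: Sequence[str],
    phenotype_token_span: tuple[int, int],
    attribute: AttributeDefinition,
    window: int = WHOLE_SENTENCE,
) -> np.ndarray:
    """Encode one phenotype context for one attribute.

    Layout: for each trigger term in :func:`trigger_inventory` order, a
    presence flag followed by the signed token distance between the trigger
    occurrence nearest the phenotype and the phenotype itself, measured
    between their facing tokens (negative = trigger to the left, 0 =
    overlapping; clipped to +-``window``, and a trigger whose nearest
    occurrence lies outside the window counts as absent). Dimensionality is
    therefore 2 x (number of trigger terms).
    """
    p_start, p_end = phenotype_token_span
    if not (0 <= p_start < p_end <= len(sentence_tokens)):
        raise PhenoSSUError(
            f"phenotype token span {phenotype_token_span} outside sentence "
            f"of {len(sentence_tokens)} tokens"
        )
    lowered = [t.lower() for t in sentence_tokens]
    inv = trigger_inventory(attribute)
    feats = np.zeros(2 * len(inv), dtype=float)
    for j, (_value, term) in enumerate(inv):
        term_toks = [t.text.lower() for t in tokenize(term)]
        L = len(term_toks)
        best = None
        for i in range(0, len(lowered) - L + 1):
            if lowered[i : i + L] == term_toks:
                if i + L - 1 < p_start:  # trigger entirely left of phenotype
                    d = (i + L - 1) - p_start
                elif i >= p_end:  # entirely right
                    d = i - (p_end - 1)
                else:  # overlapping
                    d = 0
                if best is None or abs(d) < abs(best):
                    best = d
        if best is not None and abs(best) <= window:
            feats[2 * j] = 1.0
            feats[2 * j + 1] = float(best)
    return feats


@dataclass(frozen=True)
class TrainingExample:
    features: np.ndarray
    label: str


def build_training_examples(
    corpus: Sequence[tuple[str, StandoffDocument]],
    schema: AttributeSchema,
    window: int = WHOLE_SENTENCE,
) -> dict[str, list[TrainingExample]]:
    """Per-attribute training examples from gold standoff documents: one
    example per (gold instance, attribute), labelled with the gold value."""
    examples: dict[str, list[TrainingExample]] = {a.name: [] for a in schema}
    for text, gold in corpus:
        sentences = split_sentences(text)
        instances = to_instances(gold, schema)
        for inst in instances:
            ctx = _sentence_context(text, sentences, inst.concept.span)
            if ctx is None:
                continue
            tokens, tok_span, _sent_idx = ctx
            for attr in schema:
                feats = encode_context(tokens, tok_span, attr, window)
                examples[attr.name].append(
                    TrainingExample(features=feats, label=inst.values[attr.name])
                )
    return examples


def _sentence_context(
    text: str,
    sentences: Sequence[tuple[str, tuple[int, int]]],
    span: tuple[int, int],
) -> tuple[list[str], tuple[int, int], int] | None:
    """Locate the sentence containing a character span; return its token
    strings, the phenotype's token index span, and the sentence index."""
    start, end = span
    for sent_idx, (sentence, (s_start, s_end)) in enumerate(sentences):
        if s_start <= start and end <= s_end:
            toks = tokenize(sentence)
            rel_start, rel_end = start - s_start, end - s_start
            idx = [i for i, t in enumerate(toks) if t.start < rel_end and t.end > rel_start]
            if not idx:
                return None
            return [t.text for t in toks], (idx[0], idx[-1] + 1), sent_idx
    return None


def oversample_minority(
    examples: Sequence[TrainingExample], seed: int, k_neighbors: int = 5
) -> list[TrainingExample]:
    """SMOTE-style rebalancing: every class is brought up to the majority
    count with synthetic examples interpolated between same-class nearest
    neighbours; deterministic given ``seed``. Single-class input is returned
    unchanged with a warning."""
    labels = sorted({e.label for e in examples})
    if len(labels) < 2:
        warnings.warn("oversample_minority: single-class input, returned unchanged")
        return list(examples)
    rng = np.random.default_rng(seed)
    by_label = {lab: [e for e in examples if e.label == lab] for lab in labels}
    majority = max(len(v) for v in by_label.values())
    out = list(examples)
    for lab in labels:
        members = by_label[lab]
        deficit = majority - len(members)
        if deficit <= 0:
            continue
        X = np.stack([e.features for e in members])
        if len(members) == 1:
            synth = np.repeat(X, deficit, axis=0)
        else:
            k = min(k_neighbors, len(members) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
            _, idx = nn.kneighbors(X)
            base = rng.integers(0, len(members), size=deficit)
            pick = rng.integers(1, k + 1, size=deficit)  # skip self at column 0
            gaps = rng.random(deficit)
            neigh = idx[base, pick]
            synth = X[base] + gaps[:, None] * (X[neigh] - X[base])
        out.extend(TrainingExample(features=row, label=lab) for row in synth)
    return out


class _ConstantModel:
    """Fallback for degenerate single-class training data."""

    def __init__(self, label: str):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X), dtype=object)


@dataclass
class TrainedAttributeClassifier:
    """A fitted per-attribute value predictor plus the metadata needed to
    reproduce its feature layout."""

    attribute: str
    model: object
    default_label: str
    labels: tuple[str, ...]
    feature_names: tuple[str, ...]
    window: int = WHOLE_SENTENCE
    best_params: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict_value(self, features: np.ndarray) -> str:
        return predict_value(self, features)


def train_attribute_classifier(
    examples: Sequence[TrainingExample],
    attribute: AttributeDefinition,
    grid: Mapping[str, list] | None = None,
    seed: int = 0,
    cv_folds: int = 5,
    oversample: bool = True,
) -> TrainedAttributeClassifier:
    """Fit a max-margin value classifier for one attribute.

    Minority classes are oversampled to the majority count, then the
    hyperparameters (regularization strength x kernel by default) are chosen
    by stratified cross-validated grid search on the training examples only.
    Degenerate single-class data yields a constant classifier with a warning.
    """
    if not examples:
        raise PhenoSSUError(f"no training examples for attribute {attribute.name!r}")
    inv = trigger_inventory(attribute)
    feature_names = tuple(
        f"{kind}:{value}:{term}" for value, term in inv for kind in ("presence", "distance")
    )
    labels = sorted({e.label for e in examples})
    if len(labels) < 2:
        warnings.warn(
            f"attribute {attribute.name!r}: single training class {labels[0]!r}, "
            "fitting a constant classifier"
        )
        return TrainedAttributeClassifier(
            attribute=attribute.name,
            model=_ConstantModel(labels[0]),
            default_label=attribute.default_value,
            labels=tuple(labels),
            feature_names=feature_names,
        )
    if oversample:
        examples = oversample_minority(examples, seed=seed)
    X = np.stack([e.features for e in examples])
    y = np.array([e.label for e in examples], dtype=object)
    counts = np.unique(y, return_counts=True)[1]
    folds = max(2, min(cv_folds, int(counts.min())))
    search = GridSearchCV(
        SVC(random_state=seed),
        dict(grid or DEFAULT_GRID),
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(X, y)
    return TrainedAttributeClassifier(
        attribute=attribute.name,
        model=search.best_estimator_,
        default_label=attribute.default_value,
        labels=tuple(labels),
        feature_names=feature_names,
        best_params=dict(search.best_params_),
    )


def predict_value(
    classifier: TrainedAttributeClassifier, features: np.ndarray
) -> str:
    """Predict one value label; an all-zero context (no trigger in range)
    short-circuits to the attribute's default."""
    features = np.asarray(features, dtype=float)
    if features.shape != (classifier.n_features,):
        raise PhenoSSUError(
            f"feature dimensionality mismatch for {classifier.attribute!r}: "
            f"got {features.shape}, expected ({classifier.n_features},)"
        )
    if not features.any():
        return classifier.default_label
    return str(classifier.model.predict(features[None, :])[0])


def default_baseline_predict(attribute: AttributeDefinition) -> str:
    """The reference model: always the default value — ``present`` for
    assertion, ``none`` for every other attribute — regardless of context."""
    return attribute.default_value


def train_all_attributes(
    corpus: Sequence[tuple[str, StandoffDocument]],
    schema: AttributeSchema,
    grid: Mapping[str, list] | None = None,
    seed: int = 0,
    window: int = WHOLE_SENTENCE,
) -> dict[str, TrainedAttributeClassifier]:
    examples = build_training_examples(corpus, schema, window=window)
    classifiers = {}
    for attr in schema:
        classifiers[attr.name] = train_attribute_classifier(
            examples[attr.name], attr, grid=grid, seed=seed
        )
        classifiers[attr.name].window = window
    return classifiers


def extract_phenossu(
    doc_text: str,
    lexicon: PhenotypeLexicon,
    classifiers: Mapping[str, TrainedAttributeClassifier],
    schema: AttributeSchema,
    doc_id: str = "doc",
    disease_name: str = "",
) -> PhenotypeKnowledgeGraph:
    """The hybrid extractor: dictionary concept recognition followed by
    per-attribute value prediction from each concept's sentence context.
    Attributes with no trained classifier fall back to the default-value
    baseline. Degenerate inputs yield an empty graph."""
    graph = PhenotypeKnowledgeGraph(disease_name=disease_name, source_doc=doc_id)
    if not doc_text.strip():
        return graph
    sentences = split_sentences(doc_text)
    for concept in recognize(doc_text, lexicon):
        ctx = _sentence_context(doc_text, sentences, concept.span)
        inst = new_instance(concept, schema)
        sent_idx = 0
        for attr in schema:
            clf = classifiers.get(attr.name)
            if clf is None or ctx is None:
                value = default_baseline_predict(attr)
            else:
                tokens, tok_span, sent_idx = ctx
                feats = encode_context(tokens, tok_span, attr, clf.window)
                value = predict_value(clf, feats)
            if value != attr.default_value:
                inst = set_attribute(inst, schema, attr.name, value)
        inst = replace(
            inst,
            sentence_ref=(doc_id, sent_idx),
            normalized=normalize_concept(concept),
        )
        graph.instances.append(inst)
    return graph


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_classifiers(
    model_dir: str | Path,
    classifiers: Mapping[str, TrainedAttributeClassifier],
    schema: AttributeSchema,
    seed: int,
) -> None:
    """One serialized classifier per attribute plus a manifest recording the
    schema version and training seed."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    for name, clf in classifiers.items():
        joblib.dump(clf, model_dir / f"{name}.joblib")
    manifest = {
        "schema_version": schema.version,
        "seed": seed,
        "attributes": sorted(classifiers),
    }
    (model_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )


def load_classifiers(model_dir: str | Path) -> dict[str, TrainedAttributeClassifier]:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text(encoding="utf-8"))
    return {
        name: joblib.load(model_dir / f"{name}.joblib")
        for name in manifest["attributes"]
    }
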