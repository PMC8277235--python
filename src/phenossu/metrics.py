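"""Evaluation metrics for phenotype extraction and annotation agreement.

- span-overlap precision/recall/F1 for concept recognition: a predicted
  span is a true positive when it can be paired one-to-one with an
  overlapping gold span (pairing = maximum-cardinality bipartite matching
  on the positive-overlap graph, so no valid pairing is left on the table);
- weighted accuracy per attribute = mean per-class recall over the classes
  present in the gold (balanced accuracy), which rewards getting the rare
  values right, and its unweighted mean over attributes (AWA);
- instance-level Cohen kappa over the union of span-aligned annotations,
  with raw observed agreement reported alongside;
- the precise-representation rate used for expressiveness comparisons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .model import PhenoSSUError, PhenoSSUInstance

Interval = tuple[int, int]


@dataclass(frozen=True)
class SpanEvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        tp, fp = self.true_positives, self.false_positives
        return tp / (tp + fp) if tp else 0.0

    @property
    def recall(self) -> float:
        tp, fn = self.true_positives, self.false_negatives
        return tp / (tp + fn) if tp else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def span_overlap_f1(
    predicted: Sequence[Interval], gold: Sequence[Interval]
) -> SpanEvalResult:
    """Overlap-based span evaluation.

    Predictions and gold spans are paired one-to-one; any overlap at all
    qualifies a pair. The pairing maximizes the number of matched pairs;
    unmatched predictions are false positives and unmatched gold spans are
    false negatives. Zero-denominator conventions: precision/recall/F1 are
    0 when there are no true positives.
    """
    if not predicted or not gold:
        return SpanEvalResult(0, len(predicted), len(gold))
    rows, cols = [], []
    for i, p in enumerate(predicted):
        for j, g in enumerate(gold):
            if _overlap(p, g) > 0:
                rows.append(i)
                cols.append(j)
    if not rows:
        return SpanEvalResult(0, len(predicted), len(gold))
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(predicted), len(gold)),
    )
    matching = maximum_bipartite_matching(graph, perm_type="column")
    tp = int((matching >= 0).sum())
    return SpanEvalResult(tp, len(predicted) - tp, len(gold) - tp)


def weighted_accuracy(
    predictions: Sequence[str], gold: Sequence[str], attribute: str = ""
) -> float:
    """Mean per-class recall over the classes present in the gold sequence
    (balanced accuracy); classes never seen in gold do not contribute."""
    if len(predictions) != len(gold):
        raise PhenoSSUError(
            f"prediction/gold length mismatch ({len(predictions)} vs {len(gold)})"
            + (f" for attribute {attribute!r}" if attribute else "")
        )
    if not gold:
        raise PhenoSSUError("weighted accuracy undefined on empty gold")
    recalls = []
    for cls in sorted(set(gold)):
        idx = [i for i, g in enumerate(gold) if g == cls]
        hits = sum(1 for i in idx if predictions[i] == cls)
        recalls.append(hits / len(idx))
    return float(np.mean(recalls))


@dataclass(frozen=True)
class AttributeEvalResult:
    per_attribute: Mapping[str, float]

    @property
    def average_weighted_accuracy(self) -> float:
        return average_weighted_accuracy(self.per_attribute)


def average_weighted_accuracy(per_attribute: Mapping[str, float]) -> float:
    """Unweighted mean of per-attribute weighted accuracies (AWA)."""
    if not per_attribute:
        raise PhenoSSUError("AWA undefined with no attributes evaluated")
    return float(np.mean(list(per_attribute.values())))


@dataclass(frozen=True)
class KappaResult:
    """Cohen kappa over span-aligned instances plus its raw ingredients.

    ``observed_agreement`` is the plain proportion of union items on which
    both annotators produced an identical instance; it is reported alongside
    kappa because the two are easy to conflate when agreement figures are
    quoted as fractions.
    """

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_agree: int
    n_items: int


_MISSING = "__missing__"


def _signatures(instances: Sequence[PhenoSSUInstance]) -> dict[tuple, tuple]:
    sigs: dict[tuple, tuple] = {}
    for inst in instances:
        doc = inst.sentence_ref[0] if inst.sentence_ref else ""
        key = (doc, inst.concept.span)
        sigs[key] = tuple(sorted(inst.values.items()))
    return sigs


def instance_kappa(
    instances_a: Sequence[PhenoSSUInstance],
    instances_b: Sequence[PhenoSSUInstance],
) -> KappaResult:
    """Inter-annotator agreement at the instance level.

    Items are the union of (document, span) keys from both annotators; each
    annotator's rating of an item is the full attribute assignment, or
    "missing" when that annotator has no instance at the span — so a missed
    span counts as a disagreement. kappa = (po - pe) / (1 - pe) with pe from
    the annotators' marginal rating frequencies; perfect observed agreement
    is kappa 1 by convention.
    """
    sig_a = _signatures(instances_a)
    sig_b = _signatures(instances_b)
    items = sorted(set(sig_a) | set(sig_b))
    if not items:
        raise PhenoSSUError("instance kappa undefined on an empty annotation union")
    ratings_a = [sig_a.get(k, _MISSING) for k in items]
    ratings_b = [sig_b.get(k, _MISSING) for k in items]
    n = len(items)
    n_agree = sum(1 for a, b in zip(ratings_a, ratings_b) if a == b)
    po = n_agree / n
    marg_a = Counter(ratings_a)
    marg_b = Counter(ratings_b)
    pe = sum(marg_a[c] * marg_b.get(c, 0) for c in marg_a) / (n * n)
    kappa = 1.0 if po == 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(
        kappa=kappa, observed_agreement=po, expected_agreement=pe,
        n_agree=n_agree, n_items=n,
    )


def precise_representation_rate(
    instances: Sequence[PhenoSSUInstance],
) -> tuple[int, int, float]:
    """(count_full, count_total, percentage to 1 decimal) of instances whose
    annotation captures the full semantics of the original description."""
    if not instances:
        raise PhenoSSUError("precise representation rate undefined on empty input")
    full = sum(1 for i in instances if i.equal_to_original == "full")
    total = len(instances)
    return full, total, round(100.0 * full / total, 1)


def evaluate_extraction(
    pred_by_doc: Mapping[str, Sequence[PhenoSSUInstance]],
    gold_by_doc: Mapping[str, Sequence[PhenoSSUInstance]],
    attribute_names: Sequence[str],
) -> dict:
    """End-to-end evaluation of extracted instances against gold.

    Concept recognition is scored with overlap-based span F1 pooled over
    documents. Attribute values are scored on exact-span-aligned instance
    pairs: per attribute, the weighted (balanced) accuracy over the gold
    classes present, and the unweighted mean across attributes (AWA).
    """
    tp = fp = fn = 0
    pairs: list[tuple[PhenoSSUInstance, PhenoSSUInstance]] = []
    for doc_id in sorted(set(pred_by_doc) | set(gold_by_doc)):
        pred = list(pred_by_doc.get(doc_id, ()))
        gold = list(gold_by_doc.get(doc_id, ()))
        res = span_overlap_f1(
            [p.concept.span for p in pred], [g.concept.span for g in gold]
        )
        tp += res.true_positives
        fp += res.false_positives
        fn += res.false_negatives
        gold_by_span = {g.concept.span: g for g in gold}
        for p in pred:
            g = gold_by_span.get(p.concept.span)
            if g is not None:
                pairs.append((p, g))
    span_result = SpanEvalResult(tp, fp, fn)
    per_attribute: dict[str, float] = {}
    for name in attribute_names:
        golds = [g.values[name] for _p, g in pairs]
        preds = [p.values[name] for p, _g in pairs]
        if golds:
            per_attribute[name] = weighted_accuracy(preds, golds, name)
    out = {
        "span": span_result,
        "per_attribute": per_attribute,
    }
    if per_attribute:
        out["average_weighted_accuracy"] = average_weighted_accuracy(per_attribute)
    return out


def concept_coverage(
    annotated_codes: Sequence[str], reference_codes: Sequence[str]
) -> tuple[int, int, float]:
    """Coverage of a reference concept list by an annotated concept set:
    (covered, total, percentage to 1 decimal)."""
    if not reference_codes:
        raise PhenoSSUError("coverage undefined against an empty reference")
    annotated = set(annotated_codes)
    covered = sum(1 for c in reference_codes if c in annotated)
    total = len(reference_codes)
    return covered, total, round(100.0 * covered / total, 1)
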