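"""Evaluation statistics for relation extraction and entity grounding.

Extraction output is reduced to subject–predicate–object triples (with
optional qualifiers on each part) and scored against a gold set by exact
set comparison after two filtering rules: statements whose predicate
qualifier is ``NOT`` are discarded entirely (negated relations are not
assertions), and subject/object qualifiers are cleared before matching
(benchmarks such as the chemical–disease relation task do not test for
them).  Grounding accuracy follows the single-entity protocol: a
label/identifier pair counts correct only when the label text is parsed
as one whole entity, unchanged, and grounded to exactly the gold
identifier — a truncated-span match is an error even when its identifier
happens to be right.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence, Union

from .extraction import ExtractionResult, InstanceNode, iter_values
from .grounding import GroundedRef, Placeholder, normalize_label


@dataclass(frozen=True)
class TripleRecord:
    """One subject–predicate–object statement with optional qualifiers."""

    subject: str
    predicate: str
    object: str
    subject_qualifier: Optional[str] = None
    object_qualifier: Optional[str] = None
    predicate_qualifier: Optional[str] = None
    document_id: Optional[str] = None


@dataclass(frozen=True)
class ScoreReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f_score: float


def filter_statements(triples: Iterable[TripleRecord]) -> list[TripleRecord]:
    """Drop negated statements and clear subject/object qualifiers.

    Records whose predicate qualifier is ``NOT`` (case-insensitive) are
    removed; survivors keep their order with subject and object qualifiers
    cleared.  Idempotent.
    """
    out = []
    for t in triples:
        if (t.predicate_qualifier or "").strip().casefold() == "not":
            continue
        out.append(replace(t, subject_qualifier=None, object_qualifier=None))
    return out


def _match_key(t: TripleRecord, per_document: bool):
    key = (t.subject, t.predicate, t.object)
    return (t.document_id,) + key if per_document else key


def score_triples(
    predicted: Iterable[TripleRecord],
    gold: Iterable[TripleRecord],
    *,
    per_document: bool = True,
) -> ScoreReport:
    """Precision/recall/F over exact (subject, predicate, object) matches.

    Both collections are deduplicated before matching.  With
    ``per_document`` (the default) the source document id is part of the
    match key, mirroring per-abstract relation benchmarks; corpus-level
    matching ignores it.  Zero denominators yield zero, so an empty
    prediction scores P=R=F=0 against a non-empty gold set.
    """
    pred_keys = {_match_key(t, per_document) for t in predicted}
    gold_keys = {_match_key(t, per_document) for t in gold}
    tp = len(pred_keys & gold_keys)
    fp = len(pred_keys - gold_keys)
    fn = len(gold_keys - pred_keys)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f_score = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return ScoreReport(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=precision,
        recall=recall,
        f_score=f_score,
    )


@dataclass(frozen=True)
class TermOutcome:
    label: str
    gold_curie: str
    predicted_curie: Optional[str]
    whole_span: bool
    correct: bool


@dataclass
class GroundingAccuracyReport:
    accuracy: Optional[float]  # None when the term list is empty
    outcomes: list[TermOutcome] = field(default_factory=list)


GrounderFn = Callable[[str], Union[GroundedRef, Placeholder]]


def grounding_accuracy(
    terms: Iterable[dict], grounder: GrounderFn
) -> GroundingAccuracyReport:
    """Score a grounder on (label, gold curie) pairs under the single-entity rule.

    A term is correct only if the grounder returns a :class:`GroundedRef`
    whose matched span is the whole, unchanged label and whose CURIE
    equals the gold one.  An empty term list yields an undefined (None)
    accuracy, not a vacuous 1.0.
    """
    outcomes: list[TermOutcome] = []
    for term in terms:
        label = term["label"]
        gold = term["curie"] if "curie" in term else term["gold_curie"]
        result = grounder(label)
        if isinstance(result, GroundedRef):
            whole = result.whole_span and normalize_label(
                result.matched_span or result.original_span
            ) == normalize_label(label)
            correct = whole and result.curie == gold
            outcomes.append(
                TermOutcome(
                    label=label,
                    gold_curie=gold,
                    predicted_curie=result.curie,
                    whole_span=whole,
                    correct=correct,
                )
            )
        else:
            outcomes.append(
                TermOutcome(
                    label=label,
                    gold_curie=gold,
                    predicted_curie=None,
                    whole_span=False,
                    correct=False,
                )
            )
    if not outcomes:
        return GroundingAccuracyReport(accuracy=None)
    accuracy = sum(o.correct for o in outcomes) / len(outcomes)
    return GroundingAccuracyReport(accuracy=accuracy, outcomes=outcomes)


def triples_from_result(
    result: Union[ExtractionResult, InstanceNode],
    *,
    relation_class: str = "ChemicalToDiseaseRelationship",
    document_id: Optional[str] = None,
    default_predicate: str = "INDUCES",
) -> list[TripleRecord]:
    """Collect relation triples from an extracted instance tree.

    Relationship nodes with a grounded subject and object yield one
    :class:`TripleRecord`; nodes with a placeholder on either end are
    skipped (an ungrounded entity cannot be compared against identifier
    gold standards).
    """
    root = result.root if isinstance(result, ExtractionResult) else result
    triples: list[TripleRecord] = []
    nodes = [root] + [v for _, _, v in iter_values(root) if isinstance(v, InstanceNode)]
    for node in nodes:
        if node.class_name != relation_class:
            continue
        subject = node.get("subject")
        obj = node.get("object")
        if not isinstance(subject, GroundedRef) or not isinstance(obj, GroundedRef):
            continue

        def literal(name):
            value = node.get(name)
            return getattr(value, "value", None) if value is not None else None

        predicate = literal("predicate") or default_predicate
        triples.append(
            TripleRecord(
                subject=subject.curie,
                predicate=str(predicate),
                object=obj.curie,
                subject_qualifier=literal("subject_qualifier"),
                object_qualifier=literal("object_qualifier"),
                predicate_qualifier=literal("predicate_qualifier"),
                document_id=document_id,
            )
        )
    return triples


_TRIPLE_COLUMNS = (
    "document_id",
    "subject",
    "predicate",
    "object",
    "predicate_qualifier",
    "subject_qualifier",
    "object_qualifier",
)


def write_triples_tsv(triples: Sequence[TripleRecord]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(_TRIPLE_COLUMNS)
    for t in triples:
        writer.writerow([getattr(t, c) or "" for c in _TRIPLE_COLUMNS])
    return buf.getvalue()


def read_triples_tsv(text: str) -> list[TripleRecord]:
    rows = list(csv.reader(io.StringIO(text), delimiter="\t"))
    if not rows:
        return []
    if rows[0] and rows[0][0] == "document_id":
        rows = rows[1:]
    triples = []
    for row in rows:
        if not row or not any(row):
            continue
        row = list(row) + [""] * (len(_TRIPLE_COLUMNS) - len(row))
        values = {c: (row[i] or None) for i, c in enumerate(_TRIPLE_COLUMNS)}
        triples.append(TripleRecord(**values))
    return triples


def read_pubtator(text: str, relation_type: str = "CID") -> dict[str, list[TripleRecord]]:
    """Minimal reader for the PubTator relation format.

    Returns document id → triples for lines of the shape
    ``<docid>\\tCID\\t<chemical MeSH id>\\t<disease MeSH id>``.  Entity
    annotation lines and title/abstract lines are ignored.  Provided for
    users with local copies of relation corpora; nothing in the package
    depends on it.
    """
    by_doc: dict[str, list[TripleRecord]] = {}
    for line in text.splitlines():
        parts = line.split("\t")
        if len(parts) >= 4 and parts[1] == relation_type:
            doc_id, _, subject, obj = parts[:4]
            subject = subject if ":" in subject else f"MESH:{subject}"
            obj = obj if ":" in obj else f"MESH:{obj}"
            by_doc.setdefault(doc_id, []).append(
                TripleRecord(
                    subject=subject,
                    predicate="INDUCES",
                    object=obj,
                    document_id=doc_id,
                )
            )
    return by_doc
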