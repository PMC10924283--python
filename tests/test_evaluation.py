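import random

import pytest

from groundling.evaluation import (
    ScoreReport,
    TripleRecord,
    filter_statements,
    grounding_accuracy,
    read_pubtator,
    read_triples_tsv,
    score_triples,
    write_triples_tsv,
)
from groundling.fixtures import make_grounding_protocol_fixture
from groundling.grounding import GroundedRef, Lexicon, LexiconEntry, ground_span
from groundling.schema_model import ClassDefinition

CROMAKALIM_ROW = TripleRecord(
    subject="MESH:D019806",
    predicate="INDUCES",
    object="MESH:D014664",
    object_qualifier="Large and small coronary vessels",
    document_id="2160002",
)


def test_qualified_statement_survives_with_qualifiers_cleared():
    survivors = filter_statements([CROMAKALIM_ROW])
    assert len(survivors) == 1
    kept = survivors[0]
    assert kept.object_qualifier is None and kept.subject_qualifier is None
    assert (kept.subject, kept.object) == ("MESH:D019806", "MESH:D014664")


@pytest.mark.parametrize("qualifier", ["NOT", "not", " Not "])
def test_negated_statements_are_discarded_entirely(qualifier):
    record = TripleRecord(
        subject="MESH:D008094", predicate="INDUCES", object="MESH:D006934",
        predicate_qualifier=qualifier,
    )
    assert filter_statements([CROMAKALIM_ROW, record]) == filter_statements([CROMAKALIM_ROW])


def test_filtering_empty_input_and_idempotence():
    assert filter_statements([]) == []
    once = filter_statements([CROMAKALIM_ROW])
    assert filter_statements(once) == once


def test_identical_sets_score_perfectly():
    triples = filter_statements([CROMAKALIM_ROW])
    report = score_triples(triples, triples)
    assert (report.precision, report.recall, report.f_score) == (1.0, 1.0, 1.0)


def test_partial_overlap_arithmetic():
    gold = [TripleRecord(subject=f"X:{i}", predicate="P", object="Y:1") for i in range(5)]
    predicted = gold[:2] + [
        TripleRecord(subject="X:90", predicate="P", object="Y:1"),
        TripleRecord(subject="X:91", predicate="P", object="Y:1"),
    ]
    report = score_triples(predicted, gold, per_document=False)
    assert report.precision == 0.5
    assert report.recall == 0.4
    assert report.f_score == pytest.approx(4 / 9)


def test_empty_prediction_scores_zero():
    gold = [CROMAKALIM_ROW]
    report = score_triples([], gold)
    assert (report.precision, report.recall, report.f_score) == (0.0, 0.0, 0.0)


def test_duplicate_predictions_count_once():
    triples = filter_statements([CROMAKALIM_ROW])
    report = score_triples(triples * 3, triples)
    assert report.true_positives == 1 and report.false_positives == 0


def test_per_document_matching_distinguishes_sources():
    a = TripleRecord(subject="X:1", predicate="P", object="Y:1", document_id="doc1")
    b = TripleRecord(subject="X:1", predicate="P", object="Y:1", document_id="doc2")
    assert score_triples([a], [b], per_document=True).true_positives == 0
    assert score_triples([a], [b], per_document=False).true_positives == 1


def _oracle_score(predicted, gold, per_document):
    """Nested-loop set comparison, independent of the implementation."""

    def key(t):
        k = (t.subject, t.predicate, t.object)
        return (t.document_id,) + k if per_document else k

    pred = []
    for t in predicted:
        if key(t) not in [key(p) for p in pred]:
            pred.append(t)
    gold_unique = []
    for t in gold:
        if key(t) not in [key(p) for p in gold_unique]:
            gold_unique.append(t)
    tp = sum(1 for p in pred if any(key(p) == key(q) for q in gold_unique))
    fp = len(pred) - tp
    fn = sum(1 for q in gold_unique if not any(key(p) == key(q) for p in pred))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return tp, fp, fn, precision, recall, f


def _random_triples(rng, n):
    return [
        TripleRecord(
            subject=f"X:{rng.randint(0, 6)}",
            predicate="P",
            object=f"Y:{rng.randint(0, 6)}",
            document_id=str(rng.randint(0, 2)),
        )
        for _ in range(n)
    ]


@pytest.mark.parametrize("per_document", [True, False])
def test_scoring_matches_nested_loop_oracle(per_document):
    rng = random.Random(11)
    for _ in range(300):
        predicted = _random_triples(rng, rng.randint(0, 8))
        gold = _random_triples(rng, rng.randint(0, 8))
        report = score_triples(predicted, gold, per_document=per_document)
        tp, fp, fn, p, r, f = _oracle_score(predicted, gold, per_document)
        assert (report.true_positives, report.false_positives, report.false_negatives) == (tp, fp, fn)
        assert report.precision == pytest.approx(p)
        assert report.recall == pytest.approx(r)
        assert report.f_score == pytest.approx(f)
        # harmonic mean never exceeds the arithmetic mean
        assert report.f_score <= (report.precision + report.recall) / 2 + 1e-12


def _protocol_grounder(lexicon):
    term_class = ClassDefinition(name="Term", is_named_entity=True)
    return lambda span: ground_span(span, term_class, [lexicon])


def test_grounding_protocol_full_lexicon_is_perfect():
    terms, lexicon = make_grounding_protocol_fixture(seed=0)
    report = grounding_accuracy(terms, _protocol_grounder(lexicon))
    assert report.accuracy == 1.0 and len(report.outcomes) == 20


def test_deleting_one_label_drops_exactly_that_term():
    terms, lexicon = make_grounding_protocol_fixture(seed=0)
    dropped = terms[0]["label"]
    ablated = Lexicon([e for e in lexicon.entries if e.label != dropped])
    report = grounding_accuracy(terms, _protocol_grounder(ablated))
    assert report.accuracy == pytest.approx(19 / 20)
    wrong = [o for o in report.outcomes if not o.correct]
    assert len(wrong) == 1 and wrong[0].label == dropped


def test_truncated_span_match_is_scored_incorrect():
    # lexicon only knows a truncated form, so grounding falls back to a
    # partial span: right identifier, wrong span -> incorrect
    lexicon = Lexicon(
        [LexiconEntry(label="UV-induced skin damage", curie="MESH:D012871", source_prefix="MESH")]
    )
    terms = [{"label": "UV-induced skin damage, susceptibility to", "curie": "MESH:D012871"}]
    report = grounding_accuracy(terms, _protocol_grounder(lexicon))
    assert report.accuracy == 0.0
    assert report.outcomes[0].predicted_curie == "MESH:D012871"
    assert not report.outcomes[0].whole_span


def test_empty_term_list_gives_undefined_accuracy():
    report = grounding_accuracy([], _protocol_grounder(Lexicon()))
    assert report.accuracy is None


def test_triples_tsv_round_trip():
    triples = [CROMAKALIM_ROW, TripleRecord(subject="X:1", predicate="P", object="Y:2")]
    assert read_triples_tsv(write_triples_tsv(triples)) == triples


def test_pubtator_relation_lines_parse():
    text = (
        "2160002|t|A title\n"
        "2160002|a|An abstract\n"
        "2160002\t100\t110\tcromakalim\tChemical\tD019806\n"
        "2160002\tCID\tD019806\tD014664\n"
    )
    by_doc = read_pubtator(text)
    assert by_doc == {
        "2160002": [
            TripleRecord(
                subject="MESH:D019806", predicate="INDUCES", object="MESH:D014664",
                document_id="2160002",
            )
        ]
    }
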