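import pytest
from hypothesis import given, strategies as st

import groundling as g
from groundling.extraction import (
    InvalidMergeError,
    Literal,
    ParseLog,
    PendingRef,
    empty_instance,
    merge_chunk_results,
    parse_completion,
    parse_value,
)
from groundling.fixtures import (
    instances_equal,
    make_fixture_corpus,
    render_completion,
    ungrounded_projection,
)

from conftest import WORKED_PAYLOAD, WORKED_TEXT


def test_worked_payload_parses_to_expected_pairs(recipe_schema):
    node = parse_completion(WORKED_PAYLOAD, recipe_schema, "Ingredient")
    assert node.values["food_item"] == PendingRef(span="garlic powder")
    # without a recursion callback the inlined value stays as raw text
    assert node.values["amount"] == Literal(value="2 tablespoons")


def test_inlined_attribute_triggers_one_recursive_call(recipe_schema):
    calls = []

    def recurse(class_name, text):
        calls.append((class_name, text))
        return empty_instance(recipe_schema, class_name)

    parse_completion(WORKED_PAYLOAD, recipe_schema, "Ingredient", recurse=recurse)
    assert calls == [("Quantity", "2 tablespoons")]


@pytest.mark.parametrize("key", ["Food Item", "FOOD_ITEM", "food item", "  food_item "])
def test_attribute_matching_folds_case_and_whitespace(recipe_schema, key):
    node = parse_completion(f"{key}: X", recipe_schema, "Ingredient")
    assert node.values["food_item"] == PendingRef(span="X")


def test_unmatched_lines_become_skip_records(recipe_schema):
    log = ParseLog()
    node = parse_completion(
        "no colon line\n: empty key\nunknown_attr: v", recipe_schema, "Ingredient", log=log
    )
    assert node == empty_instance(recipe_schema, "Ingredient")
    assert [r.reason for r in log.skipped] == ["no colon", "empty key", "unknown attribute 'unknown_attr'"]


def test_multivalued_value_splits_on_semicolon(recipe_schema):
    attr = recipe_schema.class_named("Recipe").attribute("categories")
    assert parse_value("onion; garlic; salt", attr, recipe_schema) == [
        Literal(value="onion"), Literal(value="garlic"), Literal(value="salt"),
    ]


def test_empty_multivalued_value_is_empty_collection(recipe_schema):
    attr = recipe_schema.class_named("Recipe").attribute("categories")
    assert parse_value("", attr, recipe_schema) == []


@pytest.mark.parametrize("null", ["None", "N/A", "not mentioned", "null", ""])
def test_null_fillers_leave_attribute_unset(recipe_schema, null):
    node = parse_completion(f"label: {null}", recipe_schema, "Recipe")
    assert "label" not in node.values


def test_bullets_and_quotes_are_stripped(recipe_schema):
    node = parse_completion('- label: "Soup"', recipe_schema, "Recipe")
    assert node.values["label"] == Literal(value="Soup")


def test_duplicate_single_valued_line_first_wins(recipe_schema):
    log = ParseLog()
    node = parse_completion("label: A\nlabel: B", recipe_schema, "Recipe", log=log)
    assert node.values["label"] == Literal(value="A")
    assert any("first wins" in w for w in log.warnings)


def test_duplicate_multivalued_lines_concatenate(recipe_schema):
    node = parse_completion("categories: a; b\ncategories: c", recipe_schema, "Recipe")
    assert node.values["categories"] == [Literal(value="a"), Literal(value="b"), Literal(value="c")]


def test_number_coercion_failure_keeps_string_with_warning():
    schema = g.load_schema("classes:\n  A:\n    attributes:\n      n: {range: number}\n")
    log = ParseLog()
    node = parse_completion("n: twelve", schema, "A", log=log)
    assert node.values["n"] == Literal(value="twelve")
    assert any("coerce" in w for w in log.warnings)
    assert parse_completion("n: 12", schema, "A").values["n"] == Literal(value=12)
    assert parse_completion("n: 1.5", schema, "A").values["n"] == Literal(value=1.5)


def test_empty_completion_yields_empty_instance(recipe_schema):
    backend = g.MockBackend()  # no entries: every completion is ""
    result = g.extract(recipe_schema, "Recipe", "anything", backend)
    assert result.root == empty_instance(recipe_schema, "Recipe")
    assert result.unresolved == []


@given(raw=st.binary(max_size=400))
def test_parser_is_total_on_arbitrary_bytes(recipe_schema, raw):
    text = raw.decode("utf-8", errors="replace")
    node = parse_completion(text, recipe_schema, "Recipe", log=ParseLog())
    assert node.class_name == "Recipe"


def test_merge_disjoint_chunks_unions_multivalued(ctd_schema):
    a = parse_completion("triples: x1", ctd_schema, "ChemicalToDiseaseDocument")
    b = parse_completion("triples: x2", ctd_schema, "ChemicalToDiseaseDocument")
    merged = merge_chunk_results([a, b], ctd_schema, "ChemicalToDiseaseDocument")
    assert len(merged.values["triples"]) == 2


def test_merge_is_idempotent_and_dedupes(recipe_schema):
    node = parse_completion("categories: a; b", recipe_schema, "Recipe")
    merged = merge_chunk_results([node, node, node], recipe_schema, "Recipe")
    assert merged.values["categories"] == node.values["categories"]


def test_merge_single_valued_conflict_keeps_first_and_records(recipe_schema):
    log = ParseLog()
    a = parse_completion("label: A", recipe_schema, "Recipe")
    b = parse_completion("label: B", recipe_schema, "Recipe")
    merged = merge_chunk_results([a, b], recipe_schema, "Recipe", log=log)
    assert merged.values["label"] == Literal(value="A")
    assert len(log.conflicts) == 1 and "'B'" in log.conflicts[0]


def test_merge_rejects_class_mismatch(recipe_schema):
    a = empty_instance(recipe_schema, "Recipe")
    b = empty_instance(recipe_schema, "Step")
    with pytest.raises(InvalidMergeError):
        merge_chunk_results([a, b], recipe_schema, "Recipe")


def test_merge_is_order_insensitive_up_to_ordering(recipe_schema):
    a = parse_completion("categories: a; b", recipe_schema, "Recipe")
    b = parse_completion("categories: b; c", recipe_schema, "Recipe")
    ab = merge_chunk_results([a, b], recipe_schema, "Recipe")
    ba = merge_chunk_results([b, a], recipe_schema, "Recipe")
    assert set(v.value for v in ab.values["categories"]) == set(
        v.value for v in ba.values["categories"]
    )


def test_parse_of_rendered_completion_is_ungrounded_projection(recipe_schema):
    corpus = make_fixture_corpus(seed=7, n_documents=20, schema_choice="recipe")
    for doc in corpus.documents:
        rendered = render_completion(doc.instance, recipe_schema)
        parsed = parse_completion(rendered, recipe_schema, "Recipe")
        assert instances_equal(parsed, ungrounded_projection(doc.instance, recipe_schema))


def test_worked_example_full_extraction(recipe_schema, worked_backend, worked_grounder):
    result = g.extract(recipe_schema, "Ingredient", WORKED_TEXT, worked_backend, worked_grounder)
    food = result.root.values["food_item"]
    assert isinstance(food, g.GroundedRef) and food.curie == "FOODON:03301844"
    amount = result.root.values["amount"]
    assert amount.class_name == "Quantity"
    assert amount.values["value"] == Literal(value="2")
    assert amount.values["unit"].curie == "UO:9000001"
    assert len(result.records) == 2  # one root call, one recursive call


def test_placeholders_are_unique_and_reported(recipe_schema, worked_backend):
    # no grounder lexicons: every named-entity span becomes a placeholder
    grounder = g.Grounder(lexicons=[])
    result = g.extract(recipe_schema, "Ingredient", WORKED_TEXT, worked_backend, grounder)
    labels = [p.label for p in result.unresolved]
    assert labels and len(labels) == len(set(labels))
    in_tree = [
        v.label for _, _, v in g.extraction.iter_values(result.root)
        if isinstance(v, g.Placeholder)
    ]
    assert sorted(in_tree) == sorted(labels)


def test_chunked_extraction_merges_documents(ctd_schema):
    corpus = make_fixture_corpus(seed=3, n_documents=2, schema_choice="ctd")
    doc = corpus.documents[0]
    config = g.ExtractionConfig(chunk=True, window=max(40, len(doc.text) + 1), overlap=10)
    result = g.extract(
        corpus.schema, "ChemicalToDiseaseDocument", doc.text,
        corpus.backend(), corpus.grounder(), config,
    )
    assert instances_equal(result.root, doc.instance)
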