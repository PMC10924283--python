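import random

import pytest
from hypothesis import given, strategies as st

from groundling.grounding import (
    GroundedRef,
    InvalidIdentifierError,
    Lexicon,
    LexiconEntry,
    MappingTable,
    Placeholder,
    UnresolvedRootError,
    build_lexicon,
    ground_span,
    normalize_identifier,
    normalize_label,
    resolve_value_set,
)
from groundling.schema_model import ClassDefinition, ValueSetSpec


def named_entity(prefixes=()):
    return ClassDefinition(name="Term", id_spaces=list(prefixes), is_named_entity=True)


def test_lexicon_lookup_is_normalization_invariant():
    lexicon = build_lexicon("FOODON:03301844\tgarlic powder\n")
    entries = lexicon.lookup("Garlic  Powder")
    assert [e.curie for e in entries] == ["FOODON:03301844"]
    assert lexicon.lookup("GARLIC POWDER.")  # terminal punctuation stripped


def test_empty_term_file_gives_empty_lexicon():
    assert len(build_lexicon("")) == 0


def test_duplicate_rows_collapse_to_best_priority():
    lexicon = build_lexicon("X:1\talpha\tlabel\t2\nX:1\talpha\tlabel\t1\n")
    assert len(lexicon) == 1
    assert lexicon.lookup("alpha")[0].priority == 1


def test_same_label_different_curies_both_retrievable():
    lexicon = build_lexicon("X:1\talpha\tlabel\t1\nY:2\talpha\tlabel\t2\n")
    assert sorted(e.curie for e in lexicon.lookup("alpha")) == ["X:1", "Y:2"]


def test_malformed_curie_rows_rejected_with_warning():
    warnings = []
    lexicon = build_lexicon("notacurie\talpha\nfoodon:1\tbeta\nX:1\tgamma\n", warnings=warnings)
    assert len(lexicon) == 1 and len(warnings) == 2


def test_worked_example_grounds_under_matching_prefix(recipe_lexicon):
    ref = ground_span("garlic powder", named_entity(["FOODON"]), [recipe_lexicon])
    assert isinstance(ref, GroundedRef)
    assert ref.curie == "FOODON:03301844" and ref.match_kind == "exact"


def test_prefix_constraint_without_mapping_gives_placeholder(recipe_lexicon):
    result = ground_span("garlic powder", named_entity(["MESH"]), [recipe_lexicon])
    assert isinstance(result, Placeholder)
    assert result.label == "GarlicPowder" and result.span == "garlic powder"


def test_mapping_rescues_foreign_prefix():
    lexicon = build_lexicon("CHEBI:46345\tfluorouracil\n")
    mapping = MappingTable([("CHEBI:46345", "MESH:D005472")])
    ref = ground_span("fluorouracil", named_entity(["MESH"]), [lexicon], mapping=mapping)
    assert isinstance(ref, GroundedRef) and ref.curie == "MESH:D005472"


def test_value_set_constraint_applies_with_id_spaces():
    lexicon = build_lexicon("X:1\talpha\nX:2\tbeta\n")
    cls = named_entity(["X"])
    ok = ground_span("alpha", cls, [lexicon], value_set=frozenset({"X:1"}))
    assert isinstance(ok, GroundedRef)
    rejected = ground_span("beta", cls, [lexicon], value_set=frozenset({"X:1"}))
    assert isinstance(rejected, Placeholder)


def test_trailing_parenthetical_fallback_is_logged():
    lexicon = build_lexicon("FOODON:03301844\tgarlic powder\n")
    log = []
    ref = ground_span(
        "garlic powder (2 tablespoons)", named_entity(["FOODON"]), [lexicon], log=log
    )
    assert isinstance(ref, GroundedRef) and ref.curie == "FOODON:03301844"
    assert ref.matched_span == "garlic powder" and not ref.whole_span
    assert any("partial-span" in entry for entry in log)


def test_trailing_token_fallback():
    lexicon = build_lexicon("MESH:D012871\tskin damage\n")
    ref = ground_span("skin damage susceptibility", named_entity(["MESH"]), [lexicon])
    assert isinstance(ref, GroundedRef) and not ref.whole_span


def _brute_force_best(span, lexicons, id_spaces):
    """Enumerate every candidate and rank by the declared tie-break."""
    candidates = []
    for lex_idx, lexicon in enumerate(lexicons):
        for entry in lexicon.entries:
            if normalize_label(entry.label) != normalize_label(span):
                continue
            if id_spaces and entry.curie.split(":")[0] not in id_spaces:
                continue
            exact = entry.label == span
            candidates.append(((0 if exact else 1, lex_idx, entry.priority, entry.curie), entry))
    if not candidates:
        return None
    return min(candidates, key=lambda c: c[0])[1].curie


def test_tie_break_matches_brute_force_enumeration():
    rng = random.Random(0)
    labels = ["alpha", "Alpha", "beta term", "gamma"]
    prefixes = ["AAA", "BBB", "CCC"]
    for _ in range(200):
        lexicons = []
        for _ in range(rng.randint(1, 3)):
            entries = [
                LexiconEntry(
                    label=rng.choice(labels),
                    curie=f"{rng.choice(prefixes)}:{rng.randint(1, 5)}",
                    source_prefix="X",
                    priority=rng.randint(1, 3),
                )
                for _ in range(rng.randint(1, 6))
            ]
            lexicons.append(Lexicon(entries))
        span = rng.choice(labels)
        id_spaces = rng.choice([[], ["AAA"], ["AAA", "BBB"]])
        result = ground_span(span, named_entity(id_spaces), lexicons)
        expected = _brute_force_best(span, lexicons, id_spaces)
        if expected is None:
            assert isinstance(result, Placeholder)
        else:
            assert isinstance(result, GroundedRef) and result.curie == expected


def test_grounding_is_deterministic(recipe_lexicon):
    cls = named_entity(["FOODON"])
    first = ground_span("garlic powder", cls, [recipe_lexicon])
    assert all(ground_span("garlic powder", cls, [recipe_lexicon]) == first for _ in range(5))


def test_normalize_identifier_identity_and_mapping():
    mapping = MappingTable([("CHEBI:46345", "MESH:D005472")])
    assert normalize_identifier("MESH:D005472", ["MESH"], mapping) == "MESH:D005472"
    assert normalize_identifier("CHEBI:46345", ["MESH"], mapping) == "MESH:D005472"
    assert normalize_identifier("CHEBI:99999", ["MESH"], mapping) is None
    with pytest.raises(InvalidIdentifierError):
        normalize_identifier("no curie here", ["MESH"], mapping)


def test_extensional_value_set_is_returned_verbatim():
    spec = ValueSetSpec(name="S", extensional=["X:A", "X:B"])
    assert resolve_value_set(spec) == frozenset({"X:A", "X:B"})


TOY_EDGES = [("X:X", "X:R"), ("X:Y", "X:R"), ("X:Z", "X:X")]


def test_intensional_include_exclude_on_toy_tree():
    spec = ValueSetSpec(name="S", intensional={"include": ["X:R"], "exclude": ["X:X"]})
    assert resolve_value_set(spec, TOY_EDGES) == frozenset({"X:R", "X:Y"})
    spec2 = ValueSetSpec(name="S", intensional={"include": ["X:X"]})
    assert resolve_value_set(spec2, TOY_EDGES) == frozenset({"X:X", "X:Z"})


def test_unknown_root_is_an_error():
    spec = ValueSetSpec(name="S", intensional={"include": ["X:NOPE"]})
    with pytest.raises(UnresolvedRootError):
        resolve_value_set(spec, TOY_EDGES)


def _reachability_oracle(edges, include, exclude):
    """Brute-force transitive closure by repeated expansion."""

    def closure(roots):
        out = set(roots)
        changed = True
        while changed:
            changed = False
            for child, parent in edges:
                if parent in out and child not in out:
                    out.add(child)
                    changed = True
        return out

    return closure(include) - closure(exclude)


@given(data=st.data())
def test_value_set_resolution_matches_reachability_oracle(data):
    n = data.draw(st.integers(min_value=2, max_value=50))
    nodes = [f"T:{i}" for i in range(n)]
    # edges only from higher to lower index: guaranteed acyclic
    edges = [
        (nodes[i], nodes[data.draw(st.integers(min_value=0, max_value=i - 1))])
        for i in range(1, n)
        for _ in range(data.draw(st.integers(min_value=1, max_value=2)))
    ]
    include = data.draw(st.lists(st.sampled_from(nodes), min_size=1, max_size=3))
    exclude = data.draw(st.lists(st.sampled_from(nodes), min_size=0, max_size=2))
    spec = ValueSetSpec(name="S", intensional={"include": include, "exclude": exclude})
    assert resolve_value_set(spec, edges) == frozenset(
        _reachability_oracle(edges, include, exclude)
    )
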