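"""Synthetic fixture corpora: schemas, lexicons, instance trees, and canned completions.

Everything the extraction pipeline consumes at test time is generated
here, deterministically under a seed, with no downloads: a recipe schema
and a chemical-to-disease schema, lexicons covering every named-entity
label the generator uses, instance trees conforming to the schemas, and a
canned-completion table keyed by exactly the prompts the prompt builder
will emit — so the mock backend behaves like a perfectly schema-obedient
language model.  This lets round-trip properties (render a known instance
to completion text, run the full pipeline, recover the instance) pin down
the parser and grounder without any live model.

What the generator deliberately does NOT emulate: hallucinated or
off-template completions, prose documents where entity mentions are
embedded in running text, and ambiguous spans grounding to several
vocabularies.  Those behaviors are covered separately by targeted parser
and grounder tests on adversarial strings.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .completion import MockBackend
from .evaluation import TripleRecord, filter_statements, write_triples_tsv
from .extraction import InstanceNode, Literal, PendingRef
from .grounding import GroundedRef, Grounder, Lexicon, build_lexicon, curie_prefix
from .prompt_builder import generate_prompt
from .schema_model import SchemaDefinition, load_schema, resolve_range


def _data_text(name: str) -> str:
    return (resources.files("groundling") / "fixtures_data" / name).read_text(encoding="utf-8")


def recipe_schema() -> SchemaDefinition:
    """The packaged recipe fixture schema (recipes, steps, ingredients, quantities)."""
    return load_schema(_data_text("recipe_schema.yaml"))


def ctd_schema() -> SchemaDefinition:
    """The packaged chemical-to-disease association fixture schema."""
    return load_schema(_data_text("ctd_schema.yaml"))


def packaged_lexicon(name: str = "recipe_lexicon.tsv") -> Lexicon:
    return build_lexicon(_data_text(name))


def packaged_ontology_edges() -> list[tuple[str, str]]:
    edges = []
    for line in _data_text("food_ontology_edges.tsv").splitlines():
        if line.startswith("#") or not line.strip():
            continue
        child, parent = line.split("\t")[:2]
        edges.append((child.strip(), parent.strip()))
    return edges


def packaged_mapping_text() -> str:
    return _data_text("chebi_mesh_mapping.tsv")


# ---------------------------------------------------------------------------
# rendering instances back to the completion text a cooperative model emits


def render_value(value) -> str:
    if isinstance(value, GroundedRef):
        return value.original_span or value.matched_label
    if isinstance(value, PendingRef):
        return value.span
    if isinstance(value, InstanceNode):
        return flat_text(value)
    if isinstance(value, Literal):
        if isinstance(value.value, bool):
            return "true" if value.value else "false"
        return str(value.value)
    return str(value)


def flat_text(node: InstanceNode) -> str:
    """The flat text fragment a nested instance occupies in its parent's completion.

    Values in attribute order joined by spaces; multivalued items joined
    by commas (the semicolon is reserved as the list delimiter one level
    up).
    """
    parts = []
    for name, value in node.values.items():
        if isinstance(value, list):
            if value:
                parts.append(", ".join(render_value(v) for v in value))
        else:
            parts.append(render_value(value))
    return " ".join(p for p in parts if p)


def render_completion(instance: InstanceNode, schema: SchemaDefinition) -> str:
    """Render an instance as the pseudo-YAML completion that parses back to it.

    One ``name: value`` line per populated attribute in schema order;
    multivalued values joined by ``"; "``; inlined child instances
    rendered as their flat text (their recursive prompt's input).
    """
    cls = schema.class_named(instance.class_name)
    lines = []
    for attr in cls.attributes:
        if attr.name not in instance.values:
            continue
        value = instance.values[attr.name]
        if isinstance(value, list):
            if not value:
                continue
            text = "; ".join(render_value(v) for v in value)
        else:
            text = render_value(value)
        if text:
            lines.append(f"{attr.name}: {text}")
    return "\n".join(lines)


def ungrounded_projection(node: InstanceNode, schema: SchemaDefinition) -> InstanceNode:
    """What a parse without recursion or grounding should produce for ``node``.

    Grounded references collapse to pending spans; inlined children
    collapse to the flat text their recursive call would receive.
    """
    out = InstanceNode(class_name=node.class_name)
    for name, value in node.values.items():

        def one(v):
            if isinstance(v, GroundedRef):
                return PendingRef(span=v.original_span)
            if isinstance(v, InstanceNode):
                return Literal(value=flat_text(v))
            return v

        out.values[name] = [one(v) for v in value] if isinstance(value, list) else one(value)
    return out


def instances_equal(a: InstanceNode, b: InstanceNode) -> bool:
    """Structural equality on class, attributes, literals, and grounded CURIEs."""
    if a.class_name != b.class_name:
        return False
    keys_a = {k for k, v in a.values.items() if v != []}
    keys_b = {k for k, v in b.values.items() if v != []}
    if keys_a != keys_b:
        return False

    def norm(v):
        if isinstance(v, GroundedRef):
            return ("ref", v.curie)
        if isinstance(v, PendingRef):
            return ("pending", v.span)
        if isinstance(v, Literal):
            return ("lit", v.value)
        if isinstance(v, InstanceNode):
            return ("node", v.class_name, tuple(sorted(
                (k, tuple(map(norm, val)) if isinstance(val, list) else norm(val))
                for k, val in v.values.items() if val != []
            )))
        return ("other", repr(v))

    return all(
        (
            [norm(x) for x in a.values[k]] == [norm(x) for x in b.values[k]]
            if isinstance(a.values[k], list) and isinstance(b.values[k], list)
            else norm(a.values[k]) == norm(b.values[k])
        )
        for k in keys_a
    )


# ---------------------------------------------------------------------------
# vocabularies

_FOOD_ADJ = ["red", "dried", "smoked", "sweet", "wild", "roasted"]
_FOOD_NOUN = ["onion", "pepper", "basil", "lentil", "carrot", "tomato", "ginger", "thyme"]

_UNITS = [
    ("tablespoons", "UO:9000001"),
    ("teaspoons", "UO:9000002"),
    ("cups", "UO:9000003"),
    ("grams", "UO:9000004"),
    ("milliliters", "UO:9000005"),
]

_UTENSILS = [
    ("whisk", "WIKIDATA:Q9000001"),
    ("saucepan", "WIKIDATA:Q9000002"),
    ("knife", "WIKIDATA:Q9000003"),
    ("bowl", "WIKIDATA:Q9000004"),
    ("spatula", "WIKIDATA:Q9000005"),
]

_ACTIONS = ["mix", "bake", "stir", "chop", "simmer"]
_CATEGORIES = ["vegetarian", "quick", "spicy", "baked"]

_CHEM_NAMES = [
    "zaviprol", "mektranil", "coradexin", "fluperidone", "tarvocaine",
    "nelibrium", "oxaventil", "quirazine", "sertaphyllin", "dromexate",
]
_DISEASE_NAMES = [
    "toxic nephropathy", "acute dizziness", "transient ataxia", "drug fever",
    "renal crisis", "cardiac murmur", "liver necrosis", "optic neuritis",
]
_OBJECT_QUALIFIERS = ["transient", "large and small coronary vessels", "severe"]
_SUBJECT_QUALIFIERS = ["chronic", "high dose"]


def _food_vocab() -> list[tuple[str, str]]:
    vocab = [("garlic powder", "FOODON:03301844")]
    i = 1
    for adj in _FOOD_ADJ:
        for noun in _FOOD_NOUN:
            vocab.append((f"{adj} {noun}", f"FOODON:{9100000 + i}"))
            i += 1
    return vocab


def _mesh_vocab() -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    chemicals = [
        ("Cromakalim", "MESH:D019806"),
        ("Pinacidil", "MESH:D020110"),
        ("Lithium", "MESH:D008094"),
        ("Fluorouracil", "MESH:D005472"),
    ] + [(name, f"MESH:D{910000 + i}") for i, name in enumerate(_CHEM_NAMES)]
    conditions = [
        ("Vasodilation", "MESH:D014664"),
        ("Hypercalcemia", "MESH:D006934"),
        ("Brain Diseases", "MESH:D001927"),
    ] + [(name, f"MESH:D{920000 + i}") for i, name in enumerate(_DISEASE_NAMES)]
    return chemicals, conditions


def _ref(label: str, curie: str) -> GroundedRef:
    return GroundedRef(
        curie=curie,
        matched_label=label,
        original_span=label,
        source_prefix=curie_prefix(curie),
        match_kind="exact",
        matched_span=label,
    )


# ---------------------------------------------------------------------------
# corpus generation


@dataclass
class DocumentFixture:
    document_id: str
    text: str
    instance: InstanceNode


@dataclass
class FixtureCorpus:
    """A self-contained synthetic evaluation corpus for one fixture schema."""

    schema: SchemaDefinition
    documents: list[DocumentFixture]
    completions: dict[str, str]
    lexicon: Lexicon
    lexicon_rows: list[tuple[str, str]] = field(default_factory=list)
    ontology_edges: list[tuple[str, str]] = field(default_factory=list)
    gold_triples: list[TripleRecord] = field(default_factory=list)

    def backend(self) -> MockBackend:
        return MockBackend(self.completions)

    def grounder(self) -> Grounder:
        return Grounder(lexicons=[self.lexicon], ontology_edges=self.ontology_edges)


def _register_completions(
    node: InstanceNode, schema: SchemaDefinition, completions: dict[str, str]
) -> None:
    prompt = generate_prompt(schema, node.class_name, flat_text(node))
    completion = render_completion(node, schema)
    existing = completions.get(prompt)
    if existing is not None and existing != completion:
        raise RuntimeError(
            f"fixture collision: prompt for {node.class_name!r} maps to two completions"
        )
    completions[prompt] = completion
    for name, value in node.values.items():
        items = value if isinstance(value, list) else [value]
        for item in items:
            if isinstance(item, InstanceNode):
                _register_completions(item, schema, completions)


def _recipe_instance(rng: random.Random, i: int, schema: SchemaDefinition) -> InstanceNode:
    foods = rng.sample(_food_vocab(), k=rng.randint(1, 3))
    ingredients = []
    for label, curie in foods:
        unit_label, unit_curie = rng.choice(_UNITS)
        amount = InstanceNode(
            class_name="Quantity",
            values={"value": Literal(value=str(rng.randint(1, 9))),
                    "unit": _ref(unit_label, unit_curie)},
        )
        ingredients.append(
            InstanceNode(
                class_name="Ingredient",
                values={"food_item": _ref(label, curie), "amount": amount},
            )
        )
    steps = []
    for action in rng.sample(_ACTIONS, k=rng.randint(1, 2)):
        utensils = [_ref(l, c) for l, c in rng.sample(_UTENSILS, k=rng.randint(1, 2))]
        steps.append(
            InstanceNode(class_name="Step", values={"action": Literal(value=action),
                                                    "utensils": utensils})
        )
    return InstanceNode(
        class_name="Recipe",
        values={
            "label": Literal(value=f"test dish {i}"),
            "description": Literal(value=f"a simple synthetic recipe number {i}"),
            "categories": [Literal(value=c) for c in rng.sample(_CATEGORIES, k=rng.randint(1, 2))],
            "ingredients": ingredients,
            "steps": steps,
        },
    )


def _ctd_instance(
    rng: random.Random, doc_id: str, chemicals, conditions
) -> tuple[InstanceNode, list[TripleRecord]]:
    n_rel = rng.randint(1, 4)
    pairs = rng.sample(
        [(c, d) for c in chemicals for d in conditions], k=n_rel
    )
    relationships = []
    raw_triples = []
    for (chem_label, chem_curie), (dis_label, dis_curie) in pairs:
        values: dict = {
            "subject": _ref(chem_label, chem_curie),
            "predicate": Literal(value="INDUCES"),
            "object": _ref(dis_label, dis_curie),
        }
        pred_q = "NOT" if rng.random() < 0.25 else None
        subj_q = rng.choice(_SUBJECT_QUALIFIERS) if rng.random() < 0.2 else None
        obj_q = rng.choice(_OBJECT_QUALIFIERS) if rng.random() < 0.3 else None
        if pred_q:
            values["predicate_qualifier"] = Literal(value=pred_q)
        if subj_q:
            values["subject_qualifier"] = Literal(value=subj_q)
        if obj_q:
            values["object_qualifier"] = Literal(value=obj_q)
        relationships.append(
            InstanceNode(class_name="ChemicalToDiseaseRelationship", values=values)
        )
        raw_triples.append(
            TripleRecord(
                subject=chem_curie,
                predicate="INDUCES",
                object=dis_curie,
                subject_qualifier=subj_q,
                object_qualifier=obj_q,
                predicate_qualifier=pred_q,
                document_id=doc_id,
            )
        )
    root = InstanceNode(
        class_name="ChemicalToDiseaseDocument", values={"triples": relationships}
    )
    return root, raw_triples


def make_fixture_corpus(
    seed: int,
    n_documents: int = 10,
    schema_choice: str = "recipe",
    out_dir: Optional[str] = None,
) -> FixtureCorpus:
    """Generate a deterministic synthetic corpus for the chosen fixture schema.

    Every instance tree conforms to the schema; the lexicon covers every
    named-entity label used; the canned-completion table is keyed by
    exactly the prompts the pipeline will generate, at every recursion
    level.  The same seed always yields byte-identical fixture files.
    """
    rng = random.Random(seed)
    completions: dict[str, str] = {}
    documents: list[DocumentFixture] = []
    gold: list[TripleRecord] = []

    if schema_choice == "recipe":
        schema = recipe_schema()
        vocab = (
            _food_vocab()
            + [(l, c) for l, c in _UNITS]
            + [("tablespoon", "UO:9000001"), ("teaspoon", "UO:9000002"),
               ("cup", "UO:9000003"), ("gram", "UO:9000004"), ("milliliter", "UO:9000005")]
            + list(_UTENSILS)
        )
        edges = [(curie, "FOODON:9000000") for _, curie in _food_vocab()]
        for i in range(n_documents):
            instance = _recipe_instance(rng, i, schema)
            _register_completions(instance, schema, completions)
            documents.append(
                DocumentFixture(
                    document_id=f"recipe-{i}", text=flat_text(instance), instance=instance
                )
            )
    elif schema_choice == "ctd":
        schema = ctd_schema()
        chemicals, conditions = _mesh_vocab()
        vocab = chemicals + conditions
        edges = []
        for i in range(n_documents):
            doc_id = f"{2000000 + seed * 1000 + i}"
            instance, raw = _ctd_instance(rng, doc_id, chemicals, conditions)
            _register_completions(instance, schema, completions)
            documents.append(
                DocumentFixture(document_id=doc_id, text=flat_text(instance), instance=instance)
            )
            gold.extend(raw)
        gold = filter_statements(gold)
    else:
        raise ValueError(f"unknown schema choice {schema_choice!r}")

    lexicon_rows = sorted(set(vocab), key=lambda pair: (pair[1], pair[0]))
    lexicon = build_lexicon([(curie, label) for label, curie in lexicon_rows])
    corpus = FixtureCorpus(
        schema=schema,
        documents=documents,
        completions=completions,
        lexicon=lexicon,
        lexicon_rows=lexicon_rows,
        ontology_edges=edges,
        gold_triples=gold,
    )
    if out_dir is not None:
        _write_corpus(corpus, Path(out_dir), schema_choice)
    return corpus


def _write_corpus(corpus: FixtureCorpus, out_dir: Path, schema_choice: str) -> None:
    from .schema_model import serialize_schema

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "schema.yaml").write_text(serialize_schema(corpus.schema), encoding="utf-8")
    lexicon_tsv = "\n".join(f"{curie}\t{label}" for label, curie in corpus.lexicon_rows) + "\n"
    (out_dir / "lexicon.tsv").write_text(lexicon_tsv, encoding="utf-8")
    if corpus.ontology_edges:
        (out_dir / "ontology_edges.tsv").write_text(
            "\n".join(f"{c}\t{p}" for c, p in corpus.ontology_edges) + "\n", encoding="utf-8"
        )
    (out_dir / "completions.yaml").write_text(
        yaml.safe_dump(corpus.completions, sort_keys=True, width=10_000), encoding="utf-8"
    )
    if corpus.gold_triples:
        (out_dir / "gold_triples.tsv").write_text(
            write_triples_tsv(corpus.gold_triples), encoding="utf-8"
        )
    docs = out_dir / "documents"
    docs.mkdir(exist_ok=True)
    for doc in corpus.documents:
        (docs / f"{doc.document_id}.txt").write_text(doc.text + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# grounding-protocol fixture


def make_grounding_protocol_fixture(seed: int = 0) -> tuple[list[dict], Lexicon]:
    """A 20-term (label, gold CURIE) list with a lexicon containing every label verbatim."""
    rng = random.Random(seed)
    chemicals, conditions = _mesh_vocab()
    pool = chemicals + conditions + _food_vocab()
    picked = rng.sample(pool, k=20)
    terms = [{"label": label, "curie": curie} for label, curie in picked]
    lexicon = build_lexicon([(curie, label) for label, curie in picked])
    return terms, lexicon
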