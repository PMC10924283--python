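# groundling

Schema-guided, recursive zero-shot knowledge extraction with ontology
grounding.

Knowledge bases in the life sciences — pathway databases, disease–chemical
knowledge graphs, even structured recipe collections — are populated by
expert curators reading free text. Large language models can read that text,
but their raw output is unstructured prose and their identifiers are
hallucination-prone. `groundling` sits between the two: given a **knowledge
schema** (classes with typed, possibly nested attributes), it turns a text
into a nested instance tree whose leaf entities are grounded to stable
ontology identifiers (CURIEs), using the language model only for what it is
good at — reading — and local vocabularies for what it is not — naming.

## The method

For a schema *S*, an entry class *C*, and a text *T*, extraction proceeds in
four steps:

1. **Prompt generation.** A deterministic prompt is assembled as
   `Instructions + AttributeTemplate(S, C) + "Text:" + T + Break`, where the
   template has one line per attribute of *C*, `name: <prompt>`, in schema
   order; attribute prompts are user-supplied or auto-derived from the name
   (`food_item` → "the food item"), and multivalued attributes announce
   "A semicolon-separated list".
2. **Completion.** The prompt goes to a pluggable backend — a live HTTP
   model endpoint, or a deterministic mock keyed by prompt for offline work.
   Long documents can first be windowed by a sliding chunker with
   break-snapping, with per-chunk results merged afterwards.
3. **Parsing and recursion.** The pseudo-YAML completion is parsed
   heuristically and *totally*: split lines at the first `:`, match
   attribute names case-insensitively with whitespace normalized to
   underscores, skip (and record) anything unmatched. Values parse by
   range: primitives are kept as-is, references to named-entity classes are
   marked for grounding, and **inlined** class ranges trigger a recursive
   prompt/complete/parse cycle on the value text — this is what lets
   arbitrarily nested schemas be populated. Recursion terminates because
   inlined ranges must form an acyclic graph (checked at schema load).
4. **Grounding.** Leaf named-entity spans are looked up against local
   lexicons (label/synonym → CURIE), optionally normalized across
   vocabularies through a single-hop mapping table, and validated against
   the class's identifier-prefix constraints (`IDSpaces`) and value sets
   (explicit lists, or ontology-branch queries resolved by transitive
   closure). A span that survives no candidate becomes an RDF blank-node
   placeholder — never a fabricated identifier.

Results render as YAML (`FOODON:03301844 ## garlic powder`), canonical
JSON, or a plain RDF instance graph in Turtle. An evaluation module scores
extracted subject–predicate–object triples against a gold set (negated
`NOT`-qualified statements discarded, subject/object qualifiers cleared,
then exact set precision/recall/F), and measures grounding accuracy under a
strict single-entity rule.

## Worked example

```python
import groundling as g
from groundling.fixtures import packaged_lexicon

schema = g.recipe_schema()
text = "garlic powder (2 tablespoons)"
backend = g.MockBackend({
    g.generate_prompt(schema, "Ingredient", text):
        "food_item: garlic powder\namount: 2 tablespoons",
    g.generate_prompt(schema, "Quantity", "2 tablespoons"):
        "value: 2\nunit: tablespoons",
})
result = g.extract(schema, "Ingredient", text, backend,
                   g.Grounder(lexicons=[packaged_lexicon()]))
print(g.render_instance(result), end="")
```

prints

```yaml
Ingredient:
  food_item: FOODON:03301844 ## garlic powder
  amount:
    value: 2
    unit: UO:9000001 ## tablespoons
```

The food item grounded to its FOODON identifier; `amount` was extracted by
a *recursive* call on the fragment "2 tablespoons" against the inlined
`Quantity` class, whose unit then grounded against the unit vocabulary.
The `examples/` directory has one short script per capability (extraction
and RDF export, relation scoring, grounding accuracy, value sets and
chunking); each prints its numbers with a note on what they mean. A thin
CLI wraps the same library: `groundling extract|ground|score --help`.

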