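# Methods

## The extraction model

`groundling` treats knowledge extraction as schema-directed prompt
interrogation. A schema is a set of classes; each class has an ordered list
of attributes with a *range* (primitive `string`/`number`/`boolean`, another
class, or a value set), a cardinality flag (`multivalued`), an optional
custom prompt, and — when the range is a class — an `inlined` flag deciding
whether the value is an embedded instance or a reference to a named entity.
Named-entity classes carry identifier constraints: `id_prefixes`, the
upper-case CURIE prefixes a grounding may use, and optionally a value set
restricting the admissible terms.

Extraction of class *C* from text *T* is the composition
`ground(parse(complete(prompt(S, C, T))))`, with `parse` re-entering the
composition for every inlined attribute value. The key assumptions are:

- **The model is only asked to read.** The prompt requests a flat
  `name: value` template; nesting comes from recursion over schema
  structure, not from asking the model for structured output. Identifiers
  are never requested from the model at all — they come from lexicons.
- **Inlined ranges are acyclic.** The recursion "text of an inlined value
  becomes the next call's input" only terminates if no class inlines itself
  transitively; this is enforced as a load-time error rather than a runtime
  depth guard, so a valid schema can never loop.
- **Completions are untrusted.** The parser is total: anything that is not
  a recognizable `name: value` line is recorded and skipped, and failure to
  ground yields a blank-node placeholder, never an invented identifier.

## Prompt layout

The emitted prompt is the byte-exact concatenation
`instructions + "\n" + template + "Text:\n" + text + "\n==="`, template
lines being `name: <prompt>\n` in schema order. Two instruction variants
are provided — "Split the following piece of text into fields in the
following format:" (the default, suited to the short fragments recursion
produces) and "From the text below, extract the following entities in the
following format:" — selectable per call; the break marker is `===`; the
angle-bracket wrapping of attribute prompts can be switched off. For a
multivalued attribute the prompt text is prefixed as
"A semicolon-separated list of …", and the parser correspondingly splits
such values on `;` (configurable per parse).

## Parsing rules and edge cases

Lines are matched to attributes case-insensitively after normalizing
whitespace runs to underscores, so `Food Item:` matches `food_item`.
Leading `-` bullets and surrounding quotes are stripped (models often emit
near-YAML). Right-hand sides in a configurable null list (`None`, `N/A`,
`not mentioned`, …) leave the attribute unset. Duplicate lines: first wins
for single-valued attributes (with a warning record), concatenation for
multivalued ones. Number coercion tries integer then decimal and, on
failure, keeps the raw string alongside a warning — extraction never drops
information because it failed to be a number. All of these irregularities
accumulate in a `ParseLog` carried on the result, so provenance survives.

Chunked documents use a sliding window (defaults 2500 characters with 250
overlap, chosen to keep prompts comfortably inside small model context
windows; both fully configurable). Window starts sit on the arithmetic
grid `k·(window − overlap)` and snap backward to the nearest sentence or
whitespace break inside the overlap region, so every character is covered
and entities are not cut mid-mention when a break exists. Per-chunk
instances merge by set-union (first-seen order) on multivalued attributes
and first-non-empty-wins on single-valued ones, conflicts recorded.

## Grounding

Matching is whole-span lexical lookup under a fixed normalization policy:
Unicode NFKC, case-fold, whitespace collapse, terminal-punctuation strip.
Candidates are gathered from all lexicons in order; when the class
restricts prefixes, foreign candidates are normalized through a single-hop
CURIE mapping table or dropped; when a value set applies, membership is
required — both constraints intersect when both are present. Ties break
deterministically: exact (unnormalized) match first, then lexicon order,
then priority (lower number wins), then lexicographically smallest CURIE.
Before giving up, a longest-prefix fallback drops a trailing parenthetical
and then trailing tokens; any such partial match is logged and carries a
`matched_span` differing from the original span, which the
grounding-accuracy protocol scores as incorrect (right identifier on the
wrong span is still a wrong parse). Fuzzy string-distance matching is
deliberately out of scope: a miss becomes a placeholder a curator can see,
which is the safer failure mode for knowledge-base population.

Intensional value sets ("include these branches, minus that sub-branch")
resolve against a child→parent edge table by reflexive-transitive closure
of the included roots minus the closure of the excluded roots; unknown
roots are an error rather than an empty set.

## Evaluation statistics

Triple scoring deduplicates both sides and compares exact
(subject, predicate, object) keys, by default including the source
document id in the key (mirroring per-abstract relation benchmarks; a
corpus-level mode ignores it). Before scoring, statements with predicate
qualifier `NOT` are discarded entirely and subject/object qualifiers are
cleared. Zero denominators are defined to give 0, so an empty prediction
scores P = R = F = 0, and an empty term list yields an *undefined*
grounding accuracy rather than a vacuous 1.0.

## The synthetic corpora

The fixture generator emulates a perfectly schema-obedient model: it draws
random instance trees from the recipe and chemical-to-disease schemas
(1–3 ingredients and 1–2 steps per recipe; 1–4 relationships per abstract,
25% of them negated with `NOT`, 20%/30% carrying subject/object
qualifiers), renders each node to the completion text its prompt should
elicit, and registers those completions under exactly the prompts the
pipeline will generate at every recursion level. Lexicons cover every
generated entity label; a handful of groundings (garlic powder →
FOODON:03301844, the Cromakalim/Lithium/Fluorouracil MeSH entries) are
real identifier pairs, while unit, utensil, and invented chemical/disease
identifiers are synthetic stand-ins and marked as such in the data files.

This design makes round-trip recovery a sharp test of the machinery — any
parsing, recursion, merging, or grounding defect breaks exact recovery —
but it says nothing about a real model's reading accuracy: the corpora
contain no hallucinations, no off-template output, and no prose context
around entity mentions. Those failure modes are exercised separately by
totality tests on random byte strings and by adversarial parser/grounder
unit tests. Published benchmark figures for this class of method depend on
specific hosted models and full external ontologies and are not
reproducible offline; the acceptance script therefore reports the
statistics the package computes on its own synthetic conditions.

## Problem sizes and numerics

The acceptance run uses 100 documents per schema for round-trip recovery,
10,000 random byte strings for parser totality, 200 random ≤50-node DAGs
for value-set semantics, 1,000 random set pairs for the scoring oracle,
50 documents for the end-to-end relation score, and the 20-term grounding
protocol — sizes at which every check runs in well under a minute on one
CPU while leaving no part of the pipeline unexercised. All randomness is
`random.Random(seed)`-driven; property tests run Hypothesis derandomized.

## Known limitations

- Tokens containing the list delimiter cannot be escaped; a value with an
  embedded `;` in a multivalued field will split.
- Identifier normalization is single-hop; mapping chains are not followed.
- The grounding fallback is prefix-based (drops trailing material only);
  a lexicon entry matching a *suffix* of the span will not be found.
- Strict-YAML/JSON function-calling backends, OWL axiomatization and
  reasoning, and live annotator services are out of scope; the RDF export
  is a plain instance graph.
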