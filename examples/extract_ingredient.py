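"""Extract a structured, grounded ingredient from a short text fragment.

Builds the recipe schema's ingredient prompt for "garlic powder
(2 tablespoons)", completes it against a deterministic mock backend (which
answers exactly like a schema-obedient language model would), parses the
pseudo-YAML completion — recursing into the inlined Quantity class — and
grounds the food item against the packaged lexicon.
"""

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
grounder = g.Grounder(lexicons=[packaged_lexicon()])

result = g.extract(schema, "Ingredient", text, backend, grounder)

print("--- prompt sent to the model ---")
print(result.records[0].prompt)
print()
print("--- grounded instance (YAML) ---")
print(g.render_instance(result), end="")
print()
print("--- the same instance as RDF (Turtle) ---")
print(g.render_rdf(result, schema), end="")

# The YAML shows the food item grounded to its FOODON identifier
# (FOODON:03301844 ## garlic powder) and the quantity as a nested instance
# whose unit grounded against the unit vocabulary; the Turtle graph holds
# one node per instance and one triple per attribute-value pair.
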