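"""Resolve an intensional value set over an ontology branch, and chunk a document.

Value sets restrict which grounded terms an attribute may take.  An
extensional set lists its identifiers; an intensional one is an ontology
query — include these branches, exclude that sub-branch — resolved by
reflexive-transitive closure over a child-parent edge table.  Long
documents are windowed with a sliding chunker whose starts snap back to
sentence/whitespace breaks, and per-chunk results are merged.
"""

from groundling.completion import chunk_text
from groundling.fixtures import packaged_ontology_edges
from groundling.grounding import resolve_value_set
from groundling.schema_model import ValueSetSpec

edges = packaged_ontology_edges()
print("ontology edges (child -> parent):")
for child, parent in edges:
    print(f"  {child} -> {parent}")

spice_branch = ValueSetSpec(name="Spices", intensional={"include": ["FOODON:9000100"]})
print("\ninclude the spice branch:", sorted(resolve_value_set(spice_branch, edges)))

no_spices = ValueSetSpec(
    name="NonSpiceFood",
    intensional={"include": ["FOODON:9000000"], "exclude": ["FOODON:9000100"]},
)
print("whole food tree minus spices:", sorted(resolve_value_set(no_spices, edges)))

text = ("A first sentence about cromakalim. " * 12).strip()
chunks = chunk_text(text, window=150, overlap=40)
print(f"\ndocument of {len(text)} characters -> {len(chunks)} chunks:")
for c in chunks:
    print(f"  [{c.start:4d}:{c.end:4d}] {c.text[:40]!r}...")

# The first value set contains the spice branch root and its descendants
# (including FOODON:03301844, garlic powder); the second contains the rest
# of the food tree.  Chunk spans overlap so no entity is lost at a window
# boundary, and starts land just after sentence breaks.
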