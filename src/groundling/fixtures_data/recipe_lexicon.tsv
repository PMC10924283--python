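# curie	label	flag	priority
# Food, unit, and utensil terms for the recipe schema.  "garlic powder" is a
# real FOODON grounding; UO:9xxxxxx and WIKIDATA:Q9xxxxxx entries are
# synthetic stand-ins for unit and utensil vocabularies.
FOODON:03301844	garlic powder	label	1
UO:9000001	tablespoon	label	1
UO:9000001	tablespoons	synonym	1
UO:9000002	teaspoon	label	1
UO:9000002	teaspoons	synonym	1
UO:9000003	cup	label	1
UO:9000003	cups	synonym	1
UO:9000004	gram	label	1
UO:9000004	grams	synonym	1
UO:9000005	milliliter	label	1
UO:9000005	milliliters	synonym	1
WIKIDATA:Q9000001	whisk	label	1
WIKIDATA:Q9000002	saucepan	label	1
WIKIDATA:Q9000003	knife	label	1
WIKIDATA:Q9000004	bowl	label	1
WIKIDATA:Q9000005	spatula	label	1
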