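# curie	label	flag	priority
# Chemical and condition terms with their MeSH identifiers.
MESH:D019806	Cromakalim	label	1
MESH:D020110	Pinacidil	label	1
MESH:D014664	Vasodilation	label	1
MESH:D008094	Lithium	label	1
MESH:D006934	Hypercalcemia	label	1
MESH:D005472	Fluorouracil	label	1
MESH:D001927	Brain Diseases	label	1
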