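# curie	label	flag	priority
# ChEBI-keyed chemical labels, used together with chebi_mesh_mapping.tsv to
# exercise identifier normalization.  CHEBI:9130001 is a synthetic stand-in.
CHEBI:46345	fluorouracil	label	1
CHEBI:9130001	cromakalim	label	1
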