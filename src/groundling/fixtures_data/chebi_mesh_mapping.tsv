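# from_curie	to_curie
# Synthetic single-hop mapping fixture: ChEBI chemicals to MeSH partners.
CHEBI:46345	MESH:D005472
CHEBI:9130001	MESH:D019806
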