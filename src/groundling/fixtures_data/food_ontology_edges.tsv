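# child	parent
# Tiny synthetic food-term hierarchy (child -> parent) for intensional
# value-set resolution.  FOODON:9000000 is a synthetic "food product" root;
# garlic powder sits under the spice branch.
FOODON:9000100	FOODON:9000000
FOODON:9000200	FOODON:9000000
FOODON:03301844	FOODON:9000100
FOODON:9000101	FOODON:9000100
FOODON:9000201	FOODON:9000200
FOODON:9000202	FOODON:9000200
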