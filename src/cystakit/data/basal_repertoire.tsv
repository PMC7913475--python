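# cystakit packaged fixture: cystatin-superfamily gene repertoire of early-emerging metazoan lineages
lineage	stefin	type2_cystatin	atypical_stefin	multidomain
Porifera	1	0	0	0
Placozoa	0	0	0	0
Ctenophora	1	1	0	0
Anthozoa	1	1	0	0
Staurozoa	1	0	0	0
Cubozoa	1	1	0	0
Scyphozoa	1	1	0	0
Hydrozoa	1	1	0	0
Polypodiozoa	1	1	0	0
Myxozoa	0	0	1	0
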