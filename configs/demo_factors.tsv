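breed	geo_origin	fci_group	genetic_cluster
breed1	EU	G1	C1
breed2	EU	G2	C1
breed3	ASIA	G1	C2
breed4	ASIA	G2	C2
breed5	AMERICA	G3	C1
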