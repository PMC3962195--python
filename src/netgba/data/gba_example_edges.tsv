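source	itype	target	sign	directed
CTNNB1	direct_regulation	AKT1	unknown	0
CTNNB1	direct_regulation	CASP3	unknown	0
CTNNB1	direct_regulation	CASP6	unknown	0
CTNNB1	direct_regulation	CDK5	unknown	0
CTNNB1	direct_regulation	CREB1	unknown	0
CTNNB1	direct_regulation	MAPK8	unknown	0
CTNNB1	direct_regulation	NR4A2	unknown	0
CTNNB1	direct_regulation	PTEN	unknown	0
CTNNB1	direct_regulation	RAC1	unknown	0
CTNNB1	direct_regulation	SMAD3	unknown	0
PAK1	direct_regulation	AKT1	unknown	0
PAK1	direct_regulation	CASP3	unknown	0
PAK1	direct_regulation	CDK5	unknown	0
PAK1	direct_regulation	RAC1	unknown	0
PAK1	direct_regulation	TP53	unknown	0
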