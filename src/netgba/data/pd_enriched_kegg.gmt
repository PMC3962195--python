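hsa04510	Focal adhesion	PRKCA	EGFR	ROCK1	XIAP	PTEN	SRC	CTNNB1	AKT1	MAPK1	FYN	RASGRF1	RAC1	RHOA	RAP1A	MAPK8	PAK1	AKT2
hsa04520	Adherens junction	EGFR	FGFR1	MAPK1	FYN	RAC1	RHOA	SMAD3	CTNND1	SRC	CTNNB1
hsa04010	MAPK signaling pathway	PRKCA	EGFR	FGFR1	TP53	AKT1	MAPK1	CASP3	RASGRF1	MAPT	RAC1	CACNA1G	RAP1A	MAPK8	PAK1	AKT2
hsa04360	Axon guidance	DCC	MAPK1	ROCK1	PLXNA1	SEMA6D	FYN	RAC1	RHOA	L1CAM	PAK1	CDK5
hsa04012	ErbB signaling pathway	PRKCA	EGFR	AKT1	MAPK1	CDKN1B	MAPK8	PAK1	SRC	AKT2
hsa04062	Chemokine signaling pathway	AKT1	MAPK1	ROCK1	TIAM1	RAC1	RHOA	RAP1A	CX3CL1	GRK5	PAK1	AKT2
hsa04310	Wnt signaling pathway	PRKCA	ROCK1	RAC1	RHOA	TP53	SMAD3	SIAH1	MAPK8	CTNNB1
hsa04722	Neurotrophin signaling pathway	AKT1	MAPK1	RAC1	RHOA	TP53	RAP1A	MAPK8	AKT2
hsa05010	Alzheimer's disease	MAPK1	APP	CASP3	NOS1	MAPT	SNCA	ADAM17	CDK5	CAPN1
hsa04530	Tight junction	PRKCA	AKT1	RHOA	PTEN	SRC	SPTAN1	CTNNB1	AKT2
hsa04115	p53 signaling pathway	CASP3	TP53	SIAH1	ATR	PTEN	ATM
hsa04370	VEGF signaling pathway	PRKCA	AKT1	MAPK1	RAC1	SRC	AKT2
hsa05014	Amyotrophic lateral sclerosis (ALS)	CASP3	NOS1	GRIA1	RAC1	TP53
hsa04540	Gap junction	PRKCA	EGFR	MAPK1	DRD1	SRC	TUBB3
hsa04620	Toll-like receptor signaling pathway	AKT1	MAPK1	RAC1	MAPK8	IL12B	AKT2
hsa04810	Regulation of actin cytoskeleton	EGFR	FGFR1	MAPK1	ROCK1	TIAM1	RAC1	RHOA	PAK1
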