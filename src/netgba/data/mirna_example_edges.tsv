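source	itype	target	sign	directed
miR-124-1	mirna_regulation	SEMA6D	unknown	1
miR-128-1	mirna_regulation	SEMA6D	unknown	1
miR-16-1	mirna_regulation	SEMA6D	unknown	1
miR-19a	mirna_regulation	SEMA6D	unknown	1
miR-23b	mirna_regulation	SEMA6D	unknown	1
miR-30a	mirna_regulation	SEMA6D	unknown	1
miR-9	mirna_regulation	SEMA6D	unknown	1
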