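AKT1
CASP3
CASP6
CDK5
CREB1
MAPK8
NR4A2
PTEN
RAC1
SMAD3
TP53
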