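# Gene Family	S1	S2
UNMAPPED	100.0	120.0
U1: Acetate kinase	10.0	8.0
U1: Acetate kinase|g__X.s__X_y	7.0	5.0
U2: Butyrate kinase	4.0	4.0
U2: Butyrate kinase|unclassified	2.0	1.0
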