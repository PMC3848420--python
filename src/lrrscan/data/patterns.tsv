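name	length	insertion_site	spec
type1	28	0	LxxLxLxx[NC]xLSxLSxEExGxLxxLRxL
type2	29	16	LxxLxLxx[NC]xLSxLSxxRExGxLxxLExL
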