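name	mode	body	tolerance	search_start	search_end
walker_a	literal	GKAGMGKT	0	0	0
walker_b	literal	LLIFDGLDEAL	0	0	0
sensor1	literal	TSR	0	198	369
axp	literal	AVP	0	370	453
wh_consensus	literal	FYAKDI	0	0	0
wh_his	position	491:H	0	0	0
nls_basic_cluster	basic_cluster	5,14	0	1	197
lrr_n_capping	spacing	23,5,6,12	0	0	0
walker_a_generic	class	[AG]xxxxGK[ST]	0	0	0
walker_b_generic	class	[LIVMF][LIVMF][LIVMF][LIVMF]DxxDE	0	0	0
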