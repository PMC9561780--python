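covariate	level	high	low
stage	I	5	24
stage	II	10	10
stage	III	9	7
nodal_status	>=N1	10	10
nodal_status	N0	13	28
differentiation	low	16	12
differentiation	well_moderate	8	29
tumor_size	<4cm	10	23
tumor_size	>=4cm	10	5
scc_antigen	<=1.5	3	17
scc_antigen	>1.5	16	17
age_group	<=50	6	25
age_group	>50	18	16
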