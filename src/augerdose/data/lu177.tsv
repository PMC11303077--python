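energy_keV	yield_per_decay	category	nuclide_part	endpoint_keV
0.03	0.30216022	AE	other	
0.2	0.65215509	AE	other	
1	0.022130983	AE	other	
6.2	0.14197427	AE	other	
55.8	0.0015794397	AE	other	
47.6	0.082526028	CE	other	
101.9	0.037886851	CE	other	
110.3	0.01071615	CE	other	
143.1	0.0059543632	CE	other	
197.7	0.0093448038	CE	other	
206.1	0.0089741024	CE	other	
133.3	1	BETA_MEAN	other	435.862
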