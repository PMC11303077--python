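energy_keV	yield_per_decay	category	nuclide_part	endpoint_keV
0.018	1.9865195	AE	other	
0.12	4.9866778	AE	other	
0.45	2.48719	AE	other	
1.2	0.78835401	AE	other	
5.5	0.69502795	AE	other	
43	0.056230868	AE	other	
3.3	0.072012138	CE	other	
17.1	0.41698697	CE	other	
20.8	0.078320801	CE	other	
23.7	0.35936624	CE	other	
25.3	0.11994303	CE	other	
40.3	0.18535045	CE	other	
46.9	0.057729721	CE	other	
66	0.054615176	CE	other	
72.6	0.028994443	CE	other	
96.3	0.029538175	CE	other	
154.3	1	BETA_MEAN	other	493.835
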