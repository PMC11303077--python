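energy_keV	yield_per_decay	category	nuclide_part	endpoint_keV
17.1	0.108568	AE	Pd103	
19.9	0.048872	AE	Pd103	
22.3	0.00656	AE	Pd103	
2.325	0.12	AE	Pd103	
0.45	5.1918208	AE	Pd103	
0.119	1.9122936	AE	Pd103	
0.034	0.051885584	AE	Pd103	
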