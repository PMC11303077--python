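energy_keV	yield_per_decay	category	nuclide_part	endpoint_keV
16.8	0.0115188	AE	Rh103m	
19.6	0.0051852	AE	Rh103m	
22.3	0.000696	AE	Rh103m	
2.325	0.8	AE	Rh103m	
0.119	4.4377064	AE	Rh103m	
0.034	0.62489365	AE	Rh103m	
16.6	0.0915	CE	Rh103m	
36.3	0.74762212	CE	Rh103m	
39.4	0.14102074	CE	Rh103m	
39.8	0.019	CE	Rh103m	
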