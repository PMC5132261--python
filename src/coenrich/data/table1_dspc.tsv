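protein	F210_dspc	F210_dnsaf	F290_dspc	F290_dnsaf	F350_dspc	F350_dnsaf	BAIT1_dspc	BAIT1_dnsaf	BAIT2_dspc	BAIT2_dnsaf	CTRL1_dspc	CTRL1_dnsaf	CTRL2_dspc	CTRL2_dnsaf
Piccolo	0		12	0.000625	0		159	0.025937	10	0.004332	0		0	
Bassoon	0		1	0.000067	0		2	0.000422	1	0.000560	0		0	
CAST2/ELKS	31	0.008277	35	0.008619	0		0		0		0		0	
Liprin alpha2	1	0.000202	2	0.000424	1	0.000117	0		0		0		0	
CASK	0		2	0.000486	0		0		0		0		0	
Git1	0		24	0.008130	0		0		0		0		0	
Git2	0		3	0.001178	0		0		0		0		0	
Munc-18	9	0.003778	3	0.001318	0		0		0		1	0.001223	0	
Daam1	1	0.000262	0		0		0		3	0.006826	0		0	
Trio	0		7	0.000598	0		2	0.000535	0		0		0	
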