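enzyme_label	substrate_id	drug_id	reported_similarity	reported_p
TYMS	dUMP	trifluridine	0.82	1.97E-03
TYMS	dUMP	floxuridine	0.79	6.38E-12
TYMS	dUMP	gemcitabine	0.69	2.26E-02
TYMS	dUMP	capecitabine	0.66	9.54E-03
TYMS	methylene-THF	pemetrexed	0.75	3.85E-04
TYMS	methylene-THF	raltitrexed	0.75	8.57E-10
TYMS	methylene-THF	pralatrexate	0.69	1.40E-09
POLA1,POLB	dATP	cladribine	0.77	1.76E-08
POLA1,POLB	dATP	clofarabine	0.72	6.50E-07
POLA1,POLB	dATP	fludarabine	0.71	1.94E-06
POLA1,POLB	dGTP	nelarabine	0.76	3.38E-09
POLA1,POLB	dCTP	cytarabine	0.75	7.13E-52
DHFR	dihydrofolate	pemetrexed	0.86	7.40E-05
DHFR	tetrahydrofolate	pralatrexate	0.82	6.48E-22
DHFR	tetrahydrofolate	methotrexate	0.78	1.88E-05
RRM1	ADP	fludarabine	0.80	2.28E-08
RRM1	ADP	clofarabine	0.73	5.95E-05
RRM1	ADP	cladribine	0.71	1.59E-02
RRM1	CDP	gemcitabine	0.77	6.06E-03
DNMT1	cytidine	azacitidine	0.97	6.01E-17
DNMT1	cytidine	decitabine	0.88	8.06E-12
IMPDH1/2	IMP	ribavirin	0.69	2.66E-05
ENPP1	deamino-NAD	ribavirin	0.69	1.02E-06
ATIC	formyl-THF	pemetrexed	0.79	7.73E-06
GART	formyl-THF	pemetrexed	0.79	7.73E-06
NME1/2	dCDP	gemcitabine	0.76	1.37E-10
XDH	hypoxanthine	allopurinol	0.69	7.90E-12
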