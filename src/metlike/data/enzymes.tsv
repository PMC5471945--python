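label	ec_numbers	protein_accessions	substrate_ids	excluded_cosubstrates
TYMS	2.1.1.45	P04818	dUMP;methylene-THF
POLA1,POLB	2.7.7.7	P09884;P06746	dATP;dGTP;dCTP
DHFR	1.5.1.3	P00374	dihydrofolate;tetrahydrofolate
RRM1	1.17.4.1	P23921	ADP;CDP
DNMT1	2.1.1.37	P26358	cytidine
IMPDH1/2	1.1.1.205	P20839;P12268	IMP
ENPP1	3.6.1.9	P22413	deamino-NAD
ATIC	2.1.2.3	P31939	formyl-THF
GART	2.1.2.2	P22102	formyl-THF
NME1/2	2.7.4.6	P15531;P22392	dCDP
XDH	1.17.3.2	P47989	hypoxanthine
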