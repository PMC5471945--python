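id	name	role	smiles
trifluridine	Trifluridine	drug	OC[C@H]1O[C@H](C[C@@H]1O)n1cc(C(F)(F)F)c(=O)[nH]c1=O
floxuridine	Floxuridine	drug	OC[C@H]1O[C@H](C[C@@H]1O)n1cc(F)c(=O)[nH]c1=O
gemcitabine	Gemcitabine	drug	Nc1ccn([C@@H]2O[C@H](CO)[C@@H](O)C2(F)F)c(=O)n1
capecitabine	Capecitabine	drug	CCCCCOC(=O)Nc1nc(=O)n(cc1F)[C@@H]1O[C@@H](C)[C@H](O)[C@H]1O
pemetrexed	Pemetrexed	drug	Nc1nc2[nH]cc(CCc3ccc(C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc3)c2c(=O)[nH]1
raltitrexed	Raltitrexed	drug	Cc1nc2ccc(CN(C)c3ccc(s3)C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc2c(=O)[nH]1
pralatrexate	Pralatrexate	drug	Nc1nc(N)c2nc(CC(CC#C)c3ccc(C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc3)cnc2n1
cladribine	Cladribine	drug	Nc1nc(Cl)nc2c1ncn2[C@H]1C[C@H](O)[C@@H](CO)O1
clofarabine	Clofarabine	drug	Nc1nc(Cl)nc2c1ncn2[C@@H]1[C@H](F)[C@@H](O)[C@H](CO)O1
fludarabine	Fludarabine	drug	Nc1nc(F)nc2c1ncn2[C@@H]1O[C@H](CO)[C@@H](O)[C@@H]1O
nelarabine	Nelarabine	drug	COc1nc(N)nc2c1ncn2[C@@H]1O[C@H](CO)[C@@H](O)[C@@H]1O
cytarabine	Cytarabine	drug	Nc1ccn([C@@H]2O[C@H](CO)[C@@H](O)[C@@H]2O)c(=O)n1
methotrexate	Methotrexate	drug	CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(cc1)C(=O)N[C@@H](CCC(O)=O)C(O)=O
azacitidine	Azacitidine	drug	Nc1ncn([C@@H]2O[C@H](CO)[C@@H](O)[C@H]2O)c(=O)n1
decitabine	Decitabine	drug	Nc1ncn([C@H]2C[C@H](O)[C@@H](CO)O2)c(=O)n1
ribavirin	Ribavirin	drug	NC(=O)c1ncn(n1)[C@@H]1O[C@H](CO)[C@@H](O)[C@H]1O
allopurinol	Allopurinol	drug	O=c1[nH]cnc2[nH]ncc12
levoleucovorin	(Levo)leucovorin	drug	Nc1nc2NC[C@@H](CNc3ccc(C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc3)N(C=O)c2c(=O)[nH]1
vidarabine	Vidarabine	drug	Nc1ncnc2c1ncn2[C@@H]1O[C@H](CO)[C@@H](O)[C@@H]1O
dUMP	dUMP	metabolite	O=c1ccn([C@H]2C[C@H](O)[C@@H](COP(O)(O)=O)O2)c(=O)[nH]1
methylene-THF	5,10-Methylene-tetrahydrofolate	metabolite	Nc1nc2NC[C@@H]3CN(c4ccc(C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc4)CN3c2c(=O)[nH]1
dATP	dATP	metabolite	Nc1ncnc2c1ncn2[C@H]1C[C@H](O)[C@@H](COP(O)(=O)OP(O)(=O)OP(O)(O)=O)O1
dGTP	dGTP	metabolite	Nc1nc2c(c(=O)[nH]1)ncn2[C@H]1C[C@H](O)[C@@H](COP(O)(=O)OP(O)(=O)OP(O)(O)=O)O1
dCTP	dCTP	metabolite	Nc1ccn(c(=O)n1)[C@H]1C[C@H](O)[C@@H](COP(O)(=O)OP(O)(=O)OP(O)(O)=O)O1
dihydrofolate	7,8-Dihydrofolate	metabolite	Nc1nc2c(c(=O)[nH]1)N=C(CNc1ccc(C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc1)CN2
tetrahydrofolate	(6S)-5,6,7,8-Tetrahydrofolate	metabolite	Nc1nc2NC[C@@H](CNc3ccc(C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc3)Nc2c(=O)[nH]1
ADP	ADP	metabolite	Nc1ncnc2c1ncn2[C@@H]1O[C@H](COP(O)(=O)OP(O)(O)=O)[C@@H](O)[C@H]1O
CDP	CDP	metabolite	Nc1ccn(c(=O)n1)[C@@H]1O[C@H](COP(O)(=O)OP(O)(O)=O)[C@@H](O)[C@H]1O
cytidine	Cytidine	metabolite	Nc1ccn([C@@H]2O[C@H](CO)[C@@H](O)[C@H]2O)c(=O)n1
IMP	IMP	metabolite	O=c1[nH]cnc2c1ncn2[C@@H]1O[C@H](COP(O)(O)=O)[C@@H](O)[C@H]1O
deamino-NAD	Deamino-NAD+	metabolite	OC(=O)c1ccc[n+](c1)[C@@H]1O[C@H](COP(O)(=O)OP(O)(=O)OC[C@H]2O[C@@H](n3cnc4c(N)ncnc34)[C@H](O)[C@@H]2O)[C@@H](O)[C@H]1O
formyl-THF	10-Formyl-tetrahydrofolate	metabolite	Nc1nc2NC[C@@H](CN(C=O)c3ccc(C(=O)N[C@@H](CCC(O)=O)C(O)=O)cc3)Nc2c(=O)[nH]1
dCDP	dCDP	metabolite	Nc1ccn(c(=O)n1)[C@H]1C[C@H](O)[C@@H](COP(O)(=O)OP(O)(O)=O)O1
hypoxanthine	Hypoxanthine	metabolite	O=c1[nH]cnc2[nH]cnc12
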