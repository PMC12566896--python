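# Hand-labelled 20-molecule scaffold fixture: 10 steroids, 10 non-steroids.
# is_steroid records whether the molecule contains the tetracyclic 6-6-6-5
# all-carbon gonane skeleton.
drug_name	smiles	is_steroid
TESTOSTERONE	CC12CCC3C(C1CCC2O)CCC4=CC(=O)CCC34C	1
ESTRADIOL	CC12CCC3C(C1CCC2O)CCC4=C3C=CC(=C4)O	1
HYDROCORTISONE	CC12CCC(=O)C=C1CCC3C2C(CC4(C3CCC4(C(=O)CO)O)C)O	1
PROGESTERONE	CC(=O)C1CCC2C1(CCC3C2CCC4=CC(=O)CCC34C)C	1
PREDNISOLONE	CC12CC(C3C(C1CCC2(C(=O)CO)O)CCC4=CC(=O)C=CC34C)O	1
ETHINYLESTRADIOL	CC12CCC3C(C1CCC2(C#C)O)CCC4=C3C=CC(=C4)O	1
CHOLESTEROL	CC(C)CCCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)O)C)C	1
SPIRONOLACTONE	CC(=O)SC1CC2=CC(=O)CCC2(C3C1C4CCC5(C4(CC3)C)CCC(=O)O5)C	1
DEXAMETHASONE	CC1CC2C3CCC4=CC(=O)C=CC4(C3(C(CC2(C1(C(=O)CO)O)C)O)F)C	1
DIGOXIGENIN	CC12CCC(CC1CCC3C2CC(C4(C3(CCC4C5=CC(=O)OC5)O)C)O)O	1
ASPIRIN	CC(=O)OC1=CC=CC=C1C(=O)O	0
IBUPROFEN	CC(C)CC1=CC=C(C=C1)C(C)C(=O)O	0
CAFFEINE	CN1C=NC2=C1C(=O)N(C(=O)N2C)C	0
PARACETAMOL	CC(=O)NC1=CC=C(C=C1)O	0
ETHANOL	CCO	0
METFORMIN	CN(C)C(=N)NC(=N)N	0
WARFARIN	CC(=O)CC(C1=CC=CC=C1)C2=C(C3=CC=CC=C3OC2=O)O	0
NAPROXEN	COC1=CC2=CC=C(C=C2C=C1)C(C)C(=O)O	0
GLUCOSE	C(C1C(C(C(C(O1)O)O)O)O)O	0
BENZYLPENICILLIN	CC1(C(N2C(S1)C(C2=O)NC(=O)CC3=CC=CC=C3)C(=O)O)C	0
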