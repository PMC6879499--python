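# Twelve anti-ageing-related benchmark compounds (well-known structures).
# Format: SMILES<TAB>compound_id
OC[C@H](O)[C@H]1OC(=O)C(O)=C1O	vitamin_C
CC1=C(/C=C/C(C)=C/C=C/C(C)=C/CO)C(C)(C)CCC1	retinol
CC1=C(/C=C/C(C)=C/C=C/C(C)=C/C(O)=O)C(C)(C)CCC1	retinoic_acid
Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1	resveratrol
CCCCCC1CCC(=O)C1CC(O)=O	LR2412
C[C@@H](O)C[C@H]1OC[C@@H](O)[C@H](O)[C@H]1O	C_xyloside
C[C@@H]1CC[C@H]2C[C@@H](/C(=C/C=C/C=C/[C@@H](C)C[C@@H](C)C(=O)[C@H](OC)[C@@H](O)/C(C)=C/[C@@H](C)C(=O)C[C@H](OC(=O)[C@@H]3CCCCN3C(=O)C(=O)[C@@]1(O)O2)[C@@H](C)C[C@@H]1CC[C@H](O)[C@@H](OC)C1)C)OC	rapamycin
CN(C)C(=N)/N=C(\N)N	metformin
CCCCCCCC(=O)Oc1ccccc1C(O)=O	C8_SA
CCCCCCCCCCCC(=O)Oc1ccccc1C(O)=O	C12_SA
CC(=O)Oc1ccccc1C(O)=O	acetylsalicylic_acid
Oc1ccccc1C(O)=O	salicylic_acid
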