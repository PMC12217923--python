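Cc1nnc2n1-c1ccc(Cl)cc1C(c1ccccc1)=NC2	Alprazolam
CN(C)CCC=C1c2ccccc2CCc2ccccc21	Amitriptyline
Clc1ccc2c(c1)C(=Nc1ccccc1O2)N1CCNCC1	Amoxapine
O=C1CC2(CCCC2)CC(=O)N1CCCCN1CCN(c2ncccn2)CC1	Buspirone
CN(C)CCCN1c2ccccc2CCc2ccc(Cl)cc21	Clomipramine
CNCCCN1c2ccccc2CCc2ccccc21	Desipramine
CN(C)CC(c1ccc(O)cc1)C1(O)CCCCC1	Desvenlafaxine
CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O	Diazepam
CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1	Fluoxetine
CN(C)CCCN1c2ccccc2CCc2ccccc21	Imipramine
OC1N=C(c2ccccc2Cl)c2cc(Cl)ccc2NC1=O	Lorazepam
CNCCC=C1c2ccccc2CCc2ccccc21	Nortriptyline
OC1N=C(c2ccccc2)c2cc(Cl)ccc2NC1=O	Oxazepam
CNCCCC1c2ccccc2C=Cc2ccccc21	Protriptyline
CC(CN(C)C)CN1c2ccccc2CCc2ccccc21	Trimipramine
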