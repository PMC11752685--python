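"""Built-in library of drug-like SMILES used by the synthetic fixture generator.

All entries parse with RDKit and have at least one heavy atom; the list is
frozen so fixture generation needs no network or external files.
"""

DRUG_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "CC(=O)Nc1ccc(O)cc1",
    "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl",
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1",
    "CN1CCC23c4c5ccc(O)c4OC2C(=O)CCC3C1C5",
    "COC(=O)C1C2CCC(CC1OC(=O)c1ccccc1)N2C",
    "CCC(=O)N(c1ccccc1)C1CCN(CC1)CCc1ccccc1",
    "CN(C)CCC(c1ccc(Br)cc1)c1ccccn1",
    "Clc1ccc(cc1)C(c1ccccn1)N1CCCCC1",
    "CC(CN1c2ccccc2Sc2ccccc21)CN(C)C",
    "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21",
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",
    "CNCCCC1c2ccccc2C=Cc2ccccc21",
    "CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21",
    "CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1",
    "O=C1NC(=O)C(N1)(c1ccccc1)c1ccccc1",
    "CCC1(CC)C(=O)NC(=O)NC1=O",
    "CCC1(c2ccccc2)C(=O)NC(=O)NC1=O",
    "NC(=O)N1c2ccccc2C=Cc2ccccc21",
    "CCCCC1(CC)C(=O)NC(=O)NC1=O",
    "OCC(CO)Nc1ccc2c(c1)C(=O)c1ccccc1C2=O",
    "Clc1ccccc1C1=NCC(=O)Nc2ccc(cc12)[N+](=O)[O-]",
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",
    "OC1N=C(c2ccccc2)c2cc(Cl)ccc2NC1=O",
    "CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO",
    "CC12CC(O)C3C(CCC4=CC(=O)CCC34C)C1CCC2C(=O)CO",
    "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O",
    "CC12CCC3C(CCc4cc(O)ccc34)C1CCC2O",
    "CC(=O)C1CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C",
    "CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2(O)C(=O)CO",
    "CCC(=O)OC1(CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C)C#C",
    "CC(C)NCC(O)COc1ccc2ccccc2c1",
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "COCCc1ccc(OCC(O)CNC(C)C)cc1",
    "CC(C)NCC(O)COc1cccc2ccccc12",
    "COc1ccccc1OCC(O)CNCCOc1ccccc1OC",
    "CCOC(=O)C1=C(C)NC(C)=C(C1c1ccccc1[N+](=O)[O-])C(=O)OC",
    "CCOC(=O)C1=C(C)NC(C)=C(C1c1cccc(c1)[N+](=O)[O-])C(=O)OC(C)C",
    "COC(=O)C1=C(C)NC(C)=C(C(=O)OCCN(C)Cc2ccccc2)C1c1cccc(c1)[N+](=O)[O-]",
    "CN(C)CCOC(=O)C(c1ccccc1)c1ccccc1",
    "CC(C)(C)NCC(O)COc1cccc2c1CC(O)C(O)C2",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "CNCC(O)c1ccc(O)c(O)c1",
    "NCC(O)c1ccc(O)c(O)c1",
    "NC(=O)c1ccc(cc1)S(=O)(=O)Nc1nccs1",
    "NS(=O)(=O)c1cc2c(cc1Cl)NC(=O)NS2(=O)=O",
    "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O",
    "CC(C)C(=O)Nc1ccc(OCC(O)CNC(C)C)cc1",
    "CCCCc1nc(Cl)c(CO)n1Cc1ccc(cc1)-c1ccccc1-c1nnn[nH]1",
    "CCCCC(=O)N(Cc1ccc(cc1)-c1ccccc1-c1nnn[nH]1)c1ccccc1C(=O)O",
    "CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O",
    "NCCCCC(NC(CCc1ccccc1)C(=O)O)C(=O)N1CCCC1C(=O)O",
    "CC(CS)C(=O)N1CCCC1C(=O)O",
    "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O",
    "CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21",
    "CC(C)c1nc(N(C)S(C)(=O)=O)nc(-c2ccc(F)cc2)c1C=CC(O)CC(O)CC(=O)O",
    "OC(=O)CC(O)CC(O)C=Cc1c(C(C)C)nc2ccccc2c1-c1ccc(F)cc1",
    "O=C(O)C1CCCCN1C(=O)C(CCC(=O)O)NC(=O)C(N)Cc1ccccc1",
    "CN1CCC(CC1)=C1c2ccccc2CCc2ccccc21",
    "COc1cc2nc(nc(N)c2cc1OC)N1CCN(CC1)C(=O)C1CCCO1",
    "COc1cc2nc(nc(N)c2cc1OC)N1CCN(CC1)C(=O)c1ccco1",
    "CN(C)CCOC(c1ccccc1)c1ccccc1",
    "Clc1ccc(cc1)C(N1CCN(CCOCCO)CC1)c1ccccc1",
    "OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O",
    "CCn1cc(C(=O)O)c(=O)c2ccc(C)nc21",
    "Cc1ccc(cc1)S(=O)(=O)NC(=O)NN1CC2CCC1CC2",
    "CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1",
    "Clc1ccc(cc1)S(=O)(=O)NC(=O)NCCC",
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "NC(Cc1ccc(O)cc1)C(=O)O",
    "OC(=O)C1CC(=O)NC(=O)N1",
    "Nc1ncnc2n(cnc12)C1OC(CO)C(O)C1O",
    "CN1CCCC1c1cccnc1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "Cn1cnc2c1c(=O)[nH]c(=O)n2C",
    "CCn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CN1C(=O)N(C)c2ncn(CC(O)CO)c2C1=O",
    "CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O",
    "CC1(C)SC2C(NC(=O)C(N)c3ccccc3)C(=O)N2C1C(=O)O",
    "CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O",
    "CON=C(c1csc(N)n1)C(=O)NC1C(=O)N2C(C(=O)O)=C(COC(C)=O)CSC12",
    "Cc1onc(-c2ccccc2)c1C(=O)NC1C(=O)N2C1SC(C)(C)C2C(=O)O",
    "CN(C)C1C(O)=C(C(N)=O)C(=O)C2(O)C(O)=C3C(=O)c4c(O)cccc4C(C)(O)C3CC12",
    "Clc1ccc(cc1)C(=O)CCCN1CCC(O)(CC1)c1ccc(Cl)cc1",
    "OCC(NC(=O)C(Cl)Cl)C(O)c1ccc(cc1)[N+](=O)[O-]",
    "Cc1ccc(N)cc1",
    "Nc1ccc(cc1)S(=O)(=O)Nc1ncccn1",
    "Nc1ccc(cc1)S(N)(=O)=O",
    "Nc1ccc(cc1)S(=O)(=O)Nc1ccccn1",
    "COc1ccc2[nH]c(nc2c1)S(=O)Cc1ncc(C)c(OC)c1C",
    "COc1ccc2[nH]c(nc2c1)S(=O)Cc1ncc(C)c(OCCCOC)c1C",
    "Cc1c(OCC(F)(F)F)ccnc1CS(=O)c1nc2ccccc2[nH]1",
    "CN(C)c1ccc(cc1)C(c1ccc(cc1)N(C)C)=C1C=CC(=[N+](C)C)C=C1",
    "CC(=O)Nc1nnc(s1)S(N)(=O)=O",
    "Nc1nc(=O)c2ncn(COCCO)c2[nH]1",
    "Nc1nc(=O)c2ncn(COC(CO)CO)c2[nH]1",
    "Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O",
    "Nc1ccn(C2OC(CO)C(O)C2(F)F)c(=O)n1",
    "Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1",
    "CC1NC(=O)c2cc(ccc2N1C)S(N)(=O)=O",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",
    "CCCCOC(=O)c1ccc(N)cc1",
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",
    "COC(=O)c1ccccc1O",
    "CC(C)NCC(O)COc1ccccc1CC=C",
    "CCCC(=O)Nc1ccc(OCC(O)CNC(C)C)c(c1)C(C)=O",
    "CN(C)C(=N)NC(=N)N",
    "CCN(CC)C(=N)NC(=N)N",
    "CC(C)(C)NC(=O)C1CN(CCN1)c1ccccc1",
    "OCC1OC(O)C(O)C(O)C1O",
    "OCC1OC(OC2C(O)C(O)C(O)OC2CO)C(O)C(O)C1O",
    "CC(=O)OCC1OC(OC(C)=O)C(OC(C)=O)C(OC(C)=O)C1OC(C)=O",
    "NC(=O)c1ccc[n+](c1)C1OC(COP(=O)([O-])OP(=O)(O)OCC2OC(n3cnc4c(N)ncnc43)C(O)C2O)C(O)C1O",
    "OC(=O)CCC(=O)O",
    "OC(=O)C(O)C(O)C(=O)O",
    "CC(O)C(=O)O",
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",
    "CC(C)(C)c1ccc(cc1)C(O)CCCN1CCC(CC1)C(O)(c1ccccc1)c1ccccc1",
    "OC(=O)c1ccc(cc1)C(O)CCCN1CCC(CC1)C(O)(c1ccccc1)c1ccccc1",
    "CCOC(=O)N1CCC(CC1)=C1c2ccc(Cl)cc2CCc2cccnc21",
    "OC(CCN1CCC(CC1)C(O)(c1ccccc1)c1ccccc1)c1ccc(cc1)C(C)(C)C",
    "CN1CCN(CC1)C1=Nc2cc(Cl)ccc2Nc2ccccc21",
    "CN1CCN(CC1)C1=Nc2ccccc2Oc2ccc(Cl)cc21",
    "Cc1ccsc1C1=CC2CCCCN2CC1",
    "CN1CCC(=C2c3ccccc3CCc3sccc32)CC1",
    "Cc1nc2ccccn2c1-c1ccc2nc(N)nc(N)c2c1",
    "Nc1nc(N)c2cc(Cc3ccc(cc3)C(=O)NC(CCC(=O)O)C(=O)O)cnc2n1",
    "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(cc1)C(=O)NC(CCC(=O)O)C(=O)O",
    "Nc1nc2nc(CNc3ccc(cc3)C(=O)NC(CCC(=O)O)C(=O)O)cnc2c(=O)[nH]1",
    "CC1CN(CC(C)N1)c1cc2n(cc(C(=O)O)c(=O)c2cc1F)-c1ccc(F)cc1F",
    "CCC1(O)CC2CN(CCc3c([nH]c4ccccc34)C2C(=O)OC)C1",
    "CC(=O)Oc1ccc2c3c1OC1C(O)C=CC4C(C2)N(C)CCC314",
    "CN1CCC23c4c5ccc(OC)c4OC2C(O)C=CC3C1C5",
    "COc1ccc2CC3N(C)CCc4cc(OC)c(OC)c(c2c1)c34",
    "CN1CCc2cc(OC)c(OC)cc2C1Cc1ccc(O)c(O)c1",
    "COc1cc2CCN(C)C(Cc3ccc(O)cc3)c2cc1OC",
    "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC",
    "CN(C)CCOCCN1c2ccccc2Sc2ccccc21",
    "CCN(CC)CCOc1ccc(cc1)C(=O)c1c(C)n(CC)c2ccccc12",
    "CCCCCCCCC=CCCCCCCCC(=O)O",
    "CCCCCCCCCCCCCCCC(=O)O",
    "OC(=O)CCCCCCCC=CCC=CCC=CCC",
    "CC(C)CCCC(C)CCCC(C)CCCC(C)(C)O",
    "CC(C)=CCCC(C)=CCO",
    "CC1CCC(C(C)C)C(O)C1",
    "CC1=CCC(CC1)C(C)(C)O",
    "CC(=O)OC1CC2CCC3C(CCC4(C)C3CC(OC(C)=O)C4C(C)CCCC(C)C)C2(C)C1",
    "CC(C)CCCC(C)C1CCC2C3CC=C4CC(O)CCC4(C)C3CCC12C",
    "CC(CCC(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CC(O)C12C",
    "CC(CCC(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CCC12C",
    "CC(CCC(=O)NCCS(=O)(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CC(O)C12C",
    "OC(=O)c1cc(O)c(O)c(O)c1",
    "COc1cc(C=CC(=O)O)ccc1O",
    "Oc1ccc(C=CC(=O)O)cc1",
    "Oc1ccc(cc1)C1Oc2cc(O)cc(O)c2CC1=O",
    "Oc1ccc(cc1)-c1cc(=O)c2c(O)cc(O)cc2o1",
    "Oc1ccc(cc1)-c1oc2cc(O)cc(O)c2c(=O)c1O",
    "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O",
    "COc1ccc(cc1O)C1CC(=O)c2c(O)cc(O)cc2O1",
    "CC(=O)c1ccc(O)cc1",
    "OCc1ccccc1",
    "Oc1ccccc1",
    "Nc1ccccc1",
    "OC(=O)c1ccccc1",
    "OC(=O)c1ccccc1O",
    "Nc1ccccc1C(=O)O",
    "CC(C)(C)NCC(O)c1cc(O)cc(O)c1",
    "CNC(C)Cc1ccccc1",
    "NC(C)Cc1ccccc1",
    "NC(C)Cc1ccc2OCOc2c1",
    "CNC(C)Cc1ccc2OCOc2c1",
    "CC(N)Cc1ccc(O)cc1",
    "NCCc1ccc(O)c(O)c1",
    "NCCc1c[nH]c2ccccc12",
    "CN(C)CCc1c[nH]c2ccccc12",
    "NCCc1c[nH]cn1",
    "OCCc1ccccc1",
    "O=C(Nc1ccc(Cl)cc1)Nc1ccccc1",
    "CN(C)C(=O)Nc1ccc(Cl)c(Cl)c1",
    "COC(=O)Nc1nc2ccc(cc2[nH]1)C(=O)c1ccccc1",
    "CCOC(=O)Nc1nc2ccc(cc2[nH]1)S(=O)CCC",
    "Cc1cccc(C)c1NC(=O)CN1CCN(CC1)CC(=O)Nc1c(C)cccc1C",
    "CC(C)(C)NCC(O)COc1ccc(cc1)CCOCC1CC1",
    "Fc1ccc(cc1)C(=O)CCCN1CCC(=CC1)c1ccc(Cl)cc1",
    "COc1ccc(CC2NCCc3cc(OC)c(OC)cc32)cc1OC",
    "O=C1CC(c2ccccc2)Oc2ccccc21",
    "O=c1cc(-c2ccccc2)oc2ccccc12",
    "Clc1cccc(Cl)c1N=C1NCCN1",
    "Oc1ccc2CC3N(CC4CC4)CCC5(CCC(=O)C=C35)c2c1",
    "CC(C)(C)NCC(O)COc1ccccc1C1CCCC1",
    "CC(C)NCC(O)COc1ccccc1OCC=C",
    "CN1CCCCC1CCO",
    "ClC(Cl)(Cl)C(O)O",
    "NC(=O)OCC(C)(C)COC(N)=O",
    "CCC(C)(C)OC(N)=O",
    "Nc1nc(=O)n(cc1F)C1CC(O)C(CO)O1",
    "O=c1cc[nH]c(=O)[nH]1",
    "Cc1c[nH]c(=O)[nH]c1=O",
    "Nc1cc[nH]c(=O)n1",
    "NC1=NC(=O)c2[nH]cnc2N1",
    "O=c1[nH]cnc2[nH]cnc12",
    "O=c1[nH]c(=O)c2[nH]cnc2[nH]1",
    "O=c1[nH]c(=O)c2[nH]c(=O)[nH]c2[nH]1",
    "CC12CC(=O)C3C(CCC4=CC(=O)C=CC43C)C1CCC2(O)C(=O)CO",
    "CC(C)C1(CCN(CC1)CCC(C#N)(c1ccc(OC)cc1)C(C)C)c1ccc(OC)cc1",
    "CCC(=O)OCC(=O)C1(O)CCC2C3CCC4=CC(=O)CCC4(C)C3C(O)CC21C",
    "CC(=O)SC1CC2=CC(=O)CCC2(C)C2CCC3(C)C(CCC3(O)C#C)C12",
    "O=C1CCC2(C)C(CCC3(C)C2CCC2(C)C3CCC2=O)C1",
    "CC(=O)OCC(=O)C1CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C",
    "O=c1[nH]cc(F)c(=O)[nH]1",
]
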