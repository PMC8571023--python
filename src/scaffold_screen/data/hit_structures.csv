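id,name,smiles
1,unithiol,[O-]S(=O)(=O)CC(S)CS.[Na+]
2,aurotioprol,OC(CS[Au])CS(=O)(=O)[O-].[Na+]
3,acamprosate,CC(=O)NCCCS(=O)(=O)O
4,menadione bisulfite,[Na+].CC1(S(=O)(=O)[O-])CC(=O)c2ccccc2C1=O
5,docusate sodium,[Na+].CCCCC(CC)COC(=O)CC(S(=O)(=O)[O-])C(=O)OCC(CC)CCCC
6,camphotamide,C[n+]1cccc(C(N)=O)c1.CC1(C)C2CCC1(CS(=O)(=O)[O-])C(=O)C2
7,dermatan sulfate (repeat unit),CC(=O)NC1C(O)OC(CO)C(OS(O)(=O)=O)C1OC1OC(C(O)=O)C(O)C(O)C1O
8,ecamsule,CC1(C)C2CCC1(CS(O)(=O)=O)C(=O)C2=Cc1ccc(cc1)C=C1C(=O)C2(CS(O)(=O)=O)CCC1C2(C)C
9,sulfamazone (approx.),CC1=C(N(C)CS(=O)(=O)O)C(=O)N(c2ccccc2)N1C.COc1ccc(NS(=O)(=O)c2ccc(N)cc2)nn1
10,cefpimizole (approx.),O=C1N2C(C(=O)[O-])=C(C[n+]3ccc(CCS(=O)(=O)[O-])cc3)CSC2C1NC(=O)C(N)c1ccccc1
11,glucosulfone,OCC(O)C(O)C(O)C(O)C(Nc1ccc(cc1)S(=O)(=O)c1ccc(cc1)NC(C(O)C(O)C(O)C(O)CO)S(O)(=O)=O)S(O)(=O)=O
12,solasulfone,OS(=O)(=O)C(Nc1ccc(cc1)S(=O)(=O)c1ccc(cc1)NC(S(O)(=O)=O)CC(c1ccccc1)S(O)(=O)=O)CC(c1ccccc1)S(O)(=O)=O
13,indocyanine green,CC1(C)C(=CC=CC=CC=C2C(C)(C)c3ccc4ccccc4c3N2CCCCS([O-])(=O)=O)N(CCCCS(=O)(=O)O)c2ccc3ccccc3c21
14,tramiprosate,NCCCS(=O)(=O)O
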