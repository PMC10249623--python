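abbreviation,name,cas,smiles,group,n_pfc,n_ch2
3:1 FTOH,"1H,1H-perfluorobutan-1-ol",375-01-9,OCC(F)(F)C(F)(F)C(F)(F)F,X:1 FTOH,3,1
3:3 FTOH,3-(perfluoropropyl)propan-1-ol,679-02-7,OCCCC(F)(F)C(F)(F)C(F)(F)F,,3,3
4:2 FTOH,"1H,1H,2H,2H-perfluorohexan-1-ol",2043-47-2,OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)F,X:2 FTOH,4,2
4:4 FTOH,4-(perfluorobutyl)butan-1-ol,3792-02-7,OCCCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,4,4
6:2 FTOH,"1H,1H,2H,2H-perfluorooctan-1-ol",647-42-7,OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,X:2 FTOH,6,2
7:1 FTOH,"1H,1H-perfluorooctan-1-ol",307-30-2,OCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,X:1 FTOH,7,1
8:2 FTOH,"1H,1H,2H,2H-perfluorodecan-1-ol",678-39-7,OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,X:2 FTOH,8,2
5:2s FTOH,"1H,1H,1H,2H-perfluoroheptan-2-ol",914637-05-1,CC(O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,5,0
4:2 FTI,"1H,1H,2H,2H-perfluorohexyl iodide",2043-55-2,ICCC(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,4,2
6:1 FTI,"1H,1H-perfluoroheptyl iodide",212563-43-4,ICC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,6,1
6:1 FTI-7H,"1H,1H,7H-perfluoroheptyl iodide",376-32-9,ICC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)F,,6,1
6:2 FTAC,"1H,1H,2H,2H-perfluorooctyl acrylate",17527-29-6,C=CC(=O)OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,6,2
4:2 FTMAC,"1H,1H,2H,2H-perfluorohexyl methacrylate",1799-84-4,CC(=C)C(=O)OCCC(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,4,2
PFBSA,perfluorobutane sulfonamide,30334-69-1,NS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,PFASA,4,0
PFHxSA,perfluorohexane sulfonamide,41997-13-1,NS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,PFASA,6,0
PFOSA,perfluorooctane sulfonamide,754-91-6,NS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,PFASA,8,0
MeFBSA,N-methyl perfluorobutane sulfonamide,68298-12-4,CNS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,N-Me FASA,4,0
MeFHxSA,N-methyl perfluorohexane sulfonamide,68259-15-4,CNS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,N-Me FASA,6,0
EtFHxSA,N-ethyl perfluorohexane sulfonamide,87988-56-5,CCNS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,6,1
MeFBSE,N-methyl perfluorobutane sulfonamidoethanol,34454-97-2,OCCN(C)S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,4,2
EtFHxSE,N-ethyl perfluorohexane sulfonamidoethanol,34455-03-3,OCCN(CC)S(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F,,6,3
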