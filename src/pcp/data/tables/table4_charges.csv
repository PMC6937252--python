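# Per-atom partial charges (e) of organic molecules: ab initio HF/STO-3G
# Mulliken, the PCP model, and semi-empirical PM3. Atom labels as printed
# (superscript indices flattened; the C2H6 "C^s" is transcribed as C3).
molecule,atom_index,atom_label,q_abinitio,q_pcp,q_pm3
C3H7OH,1,C1,-0.1788,-0.1582,-0.1065
C3H7OH,2,C2,-0.0993,-0.0889,-0.1138
C3H7OH,3,C3,0.0077,0.0175,0.0736
C3H7OH,4,O4,-0.2884,-0.3253,-0.3116
C3H7OH,5,H5,0.0614,0.0519,0.0395
C3H7OH,6,H6,0.0575,0.0523,0.0369
C3H7OH,7,H7,0.0575,0.0523,0.0369
C3H7OH,8,H8,0.0612,0.0623,0.0601
C3H7OH,9,H9,0.0612,0.0623,0.0601
C3H7OH,10,H10,0.0446,0.0523,0.0203
C3H7OH,11,H11,0.0446,0.0523,0.0203
C3H7OH,12,H12,0.1705,0.1692,0.1841
C2H6,1,C1,-0.1748,-0.1613,-0.1056
C2H6,2,H2,0.0583,0.0538,0.0352
C2H6,3,C3,-0.1748,-0.1613,-0.1056
C2H6,4,H4,0.0583,0.0538,0.0352
C2H6,5,H5,0.0583,0.0538,0.0352
C2H6,6,H6,0.0583,0.0538,0.0352
C2H6,7,H7,0.0583,0.0538,0.0352
C2H6,8,H8,0.0583,0.0538,0.0352
C2H5NH2,1,C1,-0.1788,-0.1685,-0.1114
C2H5NH2,2,C2,-0.0155,-0.0837,-0.0980
C2H5NH2,3,N3,-0.3799,-0.2857,-0.0376
C2H5NH2,4,H4,0.0600,0.0449,0.0387
C2H5NH2,5,H5,0.0694,0.0617,0.0500
C2H5NH2,6,H6,0.0564,0.0580,0.0363
C2H5NH2,7,H7,0.0605,0.0729,0.0530
C2H5NH2,8,H8,0.0415,0.0683,0.0235
C2H5NH2,9,H9,0.1438,0.1137,0.0230
C2H5NH2,10,H10,0.1426,0.1183,0.0225
i-C4H9CHO,1,C1,-0.0141,-0.0313,-0.0659
i-C4H9CHO,2,C2,-0.1291,-0.1312,-0.1856
i-C4H9CHO,3,C3,0.1382,0.1325,0.2713
i-C4H9CHO,4,O4,-0.2115,-0.2920,-0.3167
i-C4H9CHO,5,H5,0.0624,0.0599,0.0761
i-C4H9CHO,6,H6,0.0668,0.0715,0.0811
i-C4H9CHO,7,H7,0.0450,0.0566,0.0537
i-C4H9CHO,8,H8,0.0541,0.0617,0.0635
i-C4H9CHO,9,C9,-0.1821,-0.1368,-0.1167
i-C4H9CHO,10,H10,0.0595,0.0567,0.0438
i-C4H9CHO,11,H11,0.0609,0.0623,0.0446
i-C4H9CHO,12,H12,0.0576,0.0665,0.0407
i-C4H9CHO,13,C13,-0.1825,-0.1498,-0.1228
i-C4H9CHO,14,H14,0.0605,0.0569,0.0472
i-C4H9CHO,15,H15,0.0567,0.0596,0.0437
i-C4H9CHO,16,H16,0.0576,0.0568,0.0419
C2H3CH3,1,C1,-0.1412,-0.1494,-0.1721
C2H3CH3,2,H2,0.0602,0.0601,0.0796
C2H3CH3,3,C3,-0.0471,-0.0428,-0.1344
C2H3CH3,4,H4,0.0577,0.0642,0.0806
C2H3CH3,5,C5,-0.1864,-0.1705,-0.0781
C2H3CH3,6,H6,0.0581,0.0588,0.0945
C2H3CH3,7,H7,0.0638,0.0573,0.0389
C2H3CH3,8,H8,0.0674,0.0612,0.0454
C2H3CH3,9,H9,0.0674,0.0612,0.0454
CH2Cl2,1,C1,-0.0279,-0.0231,-0.1061
CH2Cl2,2,Cl2,-0.1178,-0.1212,-0.0217
CH2Cl2,3,Cl3,-0.1178,-0.1212,-0.0217
CH2Cl2,4,H4,0.1318,0.1328,0.0747
CH2Cl2,5,H5,0.1318,0.1328,0.0747
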