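# Per-atom partial charges (e) of inorganic molecules: ab initio HF/STO-3G
# Mulliken, the PCP model, and semi-empirical PM3 (blank where the source
# prints a dash). Mg(NO3)2 atom labels printed as N^1n/O^n/Mg^n are
# flattened to sequential indices 1-9.
molecule,atom_index,atom_label,q_abinitio,q_pcp,q_pm3
H2CO3,1,C1,0.4203,0.3073,0.4922
H2CO3,2,O2,-0.2797,-0.2498,-0.2440
H2CO3,3,O3,-0.2787,-0.2001,-0.3877
H2CO3,4,O4,-0.3042,-0.2655,-0.3274
H2CO3,5,H5,0.2211,0.2028,0.2248
H2CO3,6,H6,0.2212,0.2052,0.2421
H2SO4,1,S1,0.8104,1.2190,2.5083
H2SO4,2,O2,-0.3046,-0.4347,-0.6563
H2SO4,3,O3,-0.3224,-0.4109,-0.8625
H2SO4,4,O4,-0.3045,-0.4344,-0.6563
H2SO4,5,H5,0.2212,0.2359,0.2647
H2SO4,6,O6,-0.3215,-0.4108,-0.8625
H2SO4,7,H7,0.2213,0.2359,0.2646
H4P2O7,1,P1,1.2552,1.1823,2.2718
H4P2O7,2,O2,-0.5618,-0.4758,-1.0355
H4P2O7,3,P3,1.2557,1.1834,2.2719
H4P2O7,4,O4,-0.5247,-0.4778,-0.9013
H4P2O7,5,O5,-0.5245,-0.4773,-0.9013
H4P2O7,6,O6,-0.4194,-0.4280,-0.6571
H4P2O7,7,O7,-0.4195,-0.4281,-0.6571
H4P2O7,8,O8,-0.4195,-0.4280,-0.6571
H4P2O7,9,O9,-0.4193,-0.4279,-0.6570
H4P2O7,10,H10,0.1944,0.1944,0.2307
H4P2O7,11,H11,0.1945,0.1943,0.2307
H4P2O7,12,H12,0.1945,0.1943,0.2307
H4P2O7,13,H13,0.1944,0.1943,0.2306
KOH,1,K1,0.4020,0.3696,
KOH,2,O2,-0.4235,-0.3954,
KOH,3,H3,0.0214,0.0258,
ZnSO4,1,S1,0.8652,0.6479,2.4606
ZnSO4,2,O2,-0.4985,-0.4804,-0.7279
ZnSO4,3,O3,-0.4549,-0.4805,-0.7280
ZnSO4,4,O4,-0.3386,-0.2473,-0.8536
ZnSO4,5,O5,-0.3387,-0.2473,-0.8536
ZnSO4,6,Zn6,0.7654,0.8075,0.7025
H3AsO4,1,O1,-0.4267,-0.4562,-0.6908
H3AsO4,2,O2,-0.4268,-0.4564,-0.6916
H3AsO4,3,As3,1.2455,1.3972,2.0869
H3AsO4,4,O4,-0.5100,-0.5553,-0.7750
H3AsO4,5,O5,-0.4269,-0.4564,-0.6904
H3AsO4,6,H6,0.1817,0.1756,0.2538
H3AsO4,7,H7,0.1815,0.1757,0.2536
H3AsO4,8,H8,0.1817,0.1757,0.2536
H2CrO4,1,Cr1,1.3264,1.3264,-0.6982
H2CrO4,2,O2,-0.3983,-0.3960,0.1413
H2CrO4,3,O3,-0.4091,-0.4115,0.1261
H2CrO4,4,O4,-0.4693,-0.4693,-0.0192
H2CrO4,5,O5,-0.4693,-0.4693,-0.0193
H2CrO4,6,H6,0.2097,0.2098,0.2347
H2CrO4,7,H7,0.2098,0.2098,0.2347
Be(OH)2,1,Be1,0.4043,0.4065,0.6142
Be(OH)2,2,O2,-0.4163,-0.4014,-0.4999
Be(OH)2,3,O3,-0.4163,-0.4014,-0.4999
Be(OH)2,4,H4,0.2142,0.1982,0.1928
Be(OH)2,5,H5,0.2142,0.1981,0.1928
Ca(OH)2,1,Ca1,0.6688,0.7434,
Ca(OH)2,2,O2,-0.4104,-0.4408,
Ca(OH)2,3,O3,-0.4104,-0.4408,
Ca(OH)2,4,H4,0.0760,0.0691,
Ca(OH)2,5,H5,0.0760,0.0691,
Mg(NO3)2,1,N1,0.2011,0.3307,1.3790
Mg(NO3)2,2,O2,-0.1046,-0.2126,-0.5303
Mg(NO3)2,3,O3,-0.3126,-0.3090,-0.6412
Mg(NO3)2,4,O4,-0.3125,-0.3600,-0.6409
Mg(NO3)2,5,Mg5,1.0573,1.1021,0.8669
Mg(NO3)2,6,N6,0.2011,0.3307,1.3790
Mg(NO3)2,7,O7,-0.1046,-0.2126,-0.5303
Mg(NO3)2,8,O8,-0.3126,-0.3090,-0.6412
Mg(NO3)2,9,O9,-0.3125,-0.3600,-0.6409
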