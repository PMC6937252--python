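# Printed per-molecule R^2 rows of the organic charge table (PCP and PM3
# columns, each against the ab initio STO-3G column).
molecule,r2_pcp,r2_pm3
C3H7OH,0.9889,0.9269
C2H6,1.0000,1.0000
C2H5NH2,0.9504,0.3788
i-C4H9CHO,0.9490,0.8476
C2H3CH3,0.9947,0.7237
CH2Cl2,0.9995,0.5215
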