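# Total energies (eV) of inorganic molecules: PCP model vs ab initio HF/STO-3G,
# with the printed absolute (eV) and relative errors. 4-decimal transcription;
# thin-space digit grouping in the source numerals stripped.
molecule,E_pcp_eV,E_abinitio_eV,abs_error_eV,rel_error
H2CO3,-7155.0952,-7076.9631,-78.1320,0.0110
H2CrO4,-36446.2912,-36163.7056,-282.5855,0.0078
H2O,-2078.8323,-2039.8957,-38.9365,0.0191
H2SO3,-16909.1457,-16753.2530,-155.8927,0.0093
H2SO4,-18948.0702,-18757.9194,-190.1508,0.0101
H3AsO3,-66805.5319,-66185.5073,-620.0246,0.0094
H3AsO4,-68782.0119,-68198.0051,-584.0068,0.0086
H3BO3,-6820.1432,-6742.6569,-77.4863,0.0115
H3PO4,-17519.6505,-17248.9840,-270.6665,0.0157
H4P2O7,-33028.4644,-32458.7670,-569.6975,0.0176
HClO2,-16561.9385,-16342.6488,-219.2897,0.0134
HClO,-14524.6659,-14392.7375,-131.9284,0.0092
HMnO4,-39347.4315,-39005.0568,-342.3747,0.0088
HNO2,-5562.9936,-5494.3185,-68.6751,0.0125
Ca(NO3)2,-33597.2759,-33206.2661,-391.0098,0.0118
Fe(NO3)2,-49507.8507,-48953.0447,-554.8060,0.0113
FeCl2,-59291.3483,-58719.1013,-572.2470,0.0097
FeSO4,-53244.4420,-52705.0675,-539.3746,0.0102
KMnO4,-55600.1628,-55128.8243,-471.3385,0.0085
Mg(NO3)2,-20671.9748,-20343.1181,-328.8567,0.0162
MgSO4,-24402.0320,-24092.2485,-309.7835,0.0129
Na2SO4,-27615.9865,-27433.2420,-182.7445,0.0067
NaNO3,-11914.8491,-11838.2962,-76.5529,0.0065
ZnSO4,-67241.2392,-66545.2938,-695.9454,0.0105
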