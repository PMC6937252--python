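# Total energies (eV) of organic molecules: PCP model vs ab initio HF/STO-3G,
# with the printed absolute (eV) and relative errors. 4-decimal transcription;
# thin-space digit grouping in the source numerals stripped.
molecule,E_pcp_eV,E_abinitio_eV,abs_error_eV,rel_error
i-C4H9OH,-6254.0150,-6239.3850,-14.6300,0.0023
C2H5CHO,-5182.3590,-5157.1373,-25.2217,0.0049
C3H7NHC2H5,-6750.7462,-6758.0336,7.2874,-0.0011
a-C6H5C2H4OH,-10328.6413,-10309.6781,-18.9631,0.0018
i-C4H9COOH,-9304.5063,-9266.6961,-37.8103,0.0041
C5H12,-5267.6724,-5280.1681,12.4957,-0.0024
C2H5C≡CH,-4174.2857,-4164.0644,-10.2213,0.0024
C2H5CN,-4614.9641,-4594.6266,-20.3374,0.0044
c-C6H11CH3,-7326.7715,-7348.6872,21.9157,-0.0030
C5H11COOC2H5,-12433.4134,-12416.2400,-17.1734,0.0014
C3H7OC2H5,-7294.4043,-7289.1925,-5.2118,0.0007
CF4,-11863.1229,-11689.3211,-173.8019,0.0147
CH3COC4H9,-8321.4526,-8306.8374,-14.6152,0.0018
C4H9NO2,-9738.8601,-9691.7359,-47.1242,0.0048
CH2=CHCH2SH,-13933.4423,-13845.6598,-87.7825,0.0063
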