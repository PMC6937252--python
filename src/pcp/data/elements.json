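{
  "_metadata": {
    "description": "First ionization energies I and electron affinities A (eV) of neutral atoms, with Z = electron count of the neutral atom.",
    "source": "CRC Handbook of Chemistry and Physics (ionization energies); NIST/Andersen et al. electron-affinity compilation. Elements whose anion is unbound (negative A) carry the conventional estimated value and are marked anion_unbound.",
    "units": "eV"
  },
  "H":  {"Z": 1,  "I_eV": 13.5984, "A_eV": 0.7542},
  "Li": {"Z": 3,  "I_eV": 5.3917,  "A_eV": 0.6180},
  "Be": {"Z": 4,  "I_eV": 9.3227,  "A_eV": -0.52, "anion_unbound": true},
  "B":  {"Z": 5,  "I_eV": 8.2980,  "A_eV": 0.2797},
  "C":  {"Z": 6,  "I_eV": 11.2603, "A_eV": 1.2621},
  "N":  {"Z": 7,  "I_eV": 14.5341, "A_eV": -0.07, "anion_unbound": true},
  "O":  {"Z": 8,  "I_eV": 13.6181, "A_eV": 1.4611},
  "F":  {"Z": 9,  "I_eV": 17.4228, "A_eV": 3.4012},
  "Na": {"Z": 11, "I_eV": 5.1391,  "A_eV": 0.5479},
  "Mg": {"Z": 12, "I_eV": 7.6462,  "A_eV": -0.40, "anion_unbound": true},
  "Al": {"Z": 13, "I_eV": 5.9858,  "A_eV": 0.4328},
  "Si": {"Z": 14, "I_eV": 8.1517,  "A_eV": 1.3895},
  "P":  {"Z": 15, "I_eV": 10.4867, "A_eV": 0.7465},
  "S":  {"Z": 16, "I_eV": 10.3600, "A_eV": 2.0771},
  "Cl": {"Z": 17, "I_eV": 12.9676, "A_eV": 3.6127},
  "K":  {"Z": 19, "I_eV": 4.3407,  "A_eV": 0.5015},
  "Ca": {"Z": 20, "I_eV": 6.1132,  "A_eV": 0.0246},
  "Cr": {"Z": 24, "I_eV": 6.7665,  "A_eV": 0.6758},
  "Mn": {"Z": 25, "I_eV": 7.4340,  "A_eV": -0.50, "anion_unbound": true},
  "Fe": {"Z": 26, "I_eV": 7.9025,  "A_eV": 0.1510},
  "Zn": {"Z": 30, "I_eV": 9.3942,  "A_eV": -0.60, "anion_unbound": true},
  "As": {"Z": 33, "I_eV": 9.7886,  "A_eV": 0.8048},
  "Br": {"Z": 35, "I_eV": 11.8138, "A_eV": 3.3636},
  "I":  {"Z": 53, "I_eV": 10.4513, "A_eV": 3.0590}
}
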