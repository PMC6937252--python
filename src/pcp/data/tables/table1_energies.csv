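# PCP-model total energies (eV) of progressively larger molecules, with atom
# counts, from the speed/scale comparison table. Only the unambiguous PCP
# column is transcribed: in the source the comparator energies are interleaved
# with relative timing figures and cannot be split reliably. Not a validation
# surface (comparator timings are hardware-dependent).
molecule,n_atoms,E_pcp_eV
C2H5OH,9,-4163.421
C5H11ON,18,-8759.925
C8H16O2N2,28,-15363.279
C18H31O7N7,63,-42984.2817
C38H67O13N11,129,-81267.3080
C59H106O18N19,202,-123532.11
C89H160O28N26,303,-182461.09
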