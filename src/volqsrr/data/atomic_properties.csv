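element,Z,principal_quantum_number,valence_electrons,mass,vdw_volume,sanderson_en,polarizability
C,6,2,4,12.011,20.58,2.746,1.76
N,7,2,5,14.007,15.60,3.194,1.10
O,8,2,6,15.999,14.71,3.654,0.802
S,16,3,6,32.06,24.43,2.957,2.90
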