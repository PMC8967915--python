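MT-ND1
MT-ND2
MT-ND3
MT-ND4
MT-ND4L
MT-ND5
MT-ND6
MT-CO1
MT-CO2
MT-CO3
MT-ATP6
MT-ATP8
MT-CYB
MT-RNR1
MT-RNR2
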