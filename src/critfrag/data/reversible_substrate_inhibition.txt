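A1 -> 0 ; k1
0 -> A1 ; k2
A1 + A2 -> A3 ; k3
A3 -> A2 ; k4
A1 + A3 -> A4 ; k5
A4 -> A1 + A3 ; k6
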