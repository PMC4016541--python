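0 -> A2 ; k1
A2 -> 0 ; k2
A1 + A2 -> A1 + A4 ; k3
A4 + A6 -> A1 + A2 ; k4
A1 + A5 -> A5 + A6 ; k5
A4 + A5 -> A3 ; k6
A3 -> A4 + A5 ; k7
A2 + A5 -> A7 ; k8
A7 -> A2 + A5 ; k9
A4 -> 0 ; k10
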