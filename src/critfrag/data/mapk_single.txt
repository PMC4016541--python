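A + E1 -> AE1 ; k1
AE1 -> A + E1 ; k2
AE1 -> Ap + E1 ; k3
Ap + E1 -> ApE1 ; k4
ApE1 -> Ap + E1 ; k5
ApE1 -> App + E1 ; k6
App + E2 -> AppE2 ; k7
AppE2 -> App + E2 ; k8
AppE2 -> Ap + E2 ; k9
Ap + E2 -> ApE2 ; k10
ApE2 -> Ap + E2 ; k11
ApE2 -> A + E2 ; k12
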