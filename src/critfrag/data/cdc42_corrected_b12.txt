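Ec -> Em ; k1
Em -> Ec ; k2
Em + RT -> M ; k3
M -> Em + RT ; k4
Em + RD -> Em + RT ; k5
M + RD -> M + RT ; k6
RT -> RD ; k7
Ec + RT -> M ; k8
RDIm -> I + RD ; k9
I + RD -> RDIm ; k10
RDIc -> RDIm ; k11
RDIm -> RDIc ; k12
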