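# Three-compartment growth parameters, breast tumor (all rates 1/day).
a: 0.653
b: 0.0719
T_ref: 1.0
P12: 0.1
P21: 0.1
P13: 0.05
P23: 0.05
eta: 0.2
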