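# Gompertz growth constants, lung tumor (1/day).
a: 0.742
b: 0.0792
T_ref: 1.0
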