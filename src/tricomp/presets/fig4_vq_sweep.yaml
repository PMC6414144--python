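# Quiescent-volume study: initial quiescent volumes 0, 500 and 200 cm^3
# under 2.0 Gy daily fractions, 15 times; alpha1/beta1 = 4.5,
# alpha2/beta2 = 10 at beta = 0.035 /Gy^2 (documented fill-in), so
# alpha1 = 0.1575, alpha2 = 0.35 /Gy.  Initial dividing volume 500 cm^3 is
# a documented fill-in; the three quiescent volumes run independently.
growth:
  a: 0.653
  b: 0.0719
  T_ref: 1.0
transitions:
  P12: 0.1
  P21: 0.1
  P13: 0.05
  P23: 0.05
  eta: 0.2
lq:
  alpha1: 0.1575
  beta1: 0.035
  alpha2: 0.35
  beta2: 0.035
initial:
  T_A: 500.0
  T_Q: 0.0
  T_D: 0.0
integrator:
  dt_out: 0.1
control:
  threshold: 0.05
experiment:
  name: quiescent_sweep
  vq_values: [0.0, 500.0, 200.0]
  dose: 2.0
  n_fractions: 15
  gap: 1.0
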