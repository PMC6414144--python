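# Fraction-size study: daily fractions of 1.2, 2.0 and 3.0 Gy on the breast
# three-compartment tumor.  Radiosensitivity is specified by ratio
# (alpha1/beta1 = 10, alpha2/beta2 = 6.6); beta = 0.035 /Gy^2 pins the
# absolute scale (documented fill-in), so alpha1 = 0.35, alpha2 = 0.231 /Gy.
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
  alpha1: 0.35
  beta1: 0.035
  alpha2: 0.231
  beta2: 0.035
initial:
  T_A: 500.0
  T_Q: 200.0
  T_D: 0.0
integrator:
  dt_out: 0.1
control:
  threshold: 0.05
experiment:
  name: dose_sweep
  doses: [1.2, 2.0, 3.0]
  policy: fixed_count
  n_fractions: 30
  gap: 1.0
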