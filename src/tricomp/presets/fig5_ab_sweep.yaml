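# Radiosensitivity study: 3.0 Gy daily fractions, 10 times, sweeping the
# quiescent-cell alpha/beta ratio at fixed beta = 0.035 /Gy^2 and fixed
# dividing-cell ratio 10 (both documented fill-ins; the published study
# names only the dose and fraction count).
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
  name: alpha_beta_sweep
  ratio_pairs: [[10.0, 3.0], [10.0, 6.6], [10.0, 10.0]]
  dose: 3.0
  n_fractions: 10
  gap: 1.0
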