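# Untreated growth comparison, lung parameters (see fig2_breast).
integrator:
  dt_out: 0.1
experiment:
  name: compare_growth
  pair: lung
  t_end: 100.0
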