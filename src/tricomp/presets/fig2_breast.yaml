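# Untreated growth comparison, breast parameters: classical Gompertz vs the
# three-compartment model, from a 1 cm^3 dividing-cell seed (a documented
# fill-in; the published comparison does not state its initial volume).
integrator:
  dt_out: 0.1
experiment:
  name: compare_growth
  pair: breast
  t_end: 100.0
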