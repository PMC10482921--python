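{
  "description": "Frozen Monte-Carlo surface-oracle contact area for the reference clot (D=12.7 mm, h=2.6 mm, L=13.8 mm); computed once with seed 12345, n=2e7.",
  "D_m": 0.0127,
  "h_m": 0.0026,
  "L_m": 0.0138,
  "seed": 12345,
  "n": 20000000,
  "contact_area_m2": 0.00013034883067765686
}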