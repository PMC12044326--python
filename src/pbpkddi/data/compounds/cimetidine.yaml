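# Cimetidine: weak CYP3A4 inhibitor (index perpetrator).
name: cimetidine
mw: 252.3
logp: 0.4
compound_class: monoprotic base
pka: 6.8
bp_ratio: 0.98
fu_plasma: 0.78
binding_protein: albumin
provenance: literature PK; weak-inhibitor Ki from in-vitro reports
absorption:
  model: first_order
  ka: 1.5
  fa: 0.8
  fu_gut: 1.0
  qgut: 15.0
distribution:
  vss: 1.0
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 30.0
  cl_renal: 18.0
  fm_map: {}
interaction:
  ki_map:
    CYP3A4: 135.0
  fu_mic_map:
    CYP3A4: 1.0
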