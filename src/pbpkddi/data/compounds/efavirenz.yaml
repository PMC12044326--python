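# Efavirenz: moderate CYP3A4 inducer (index perpetrator).
name: efavirenz
mw: 315.7
logp: 4.6
compound_class: neutral
bp_ratio: 0.74
fu_plasma: 0.01
binding_protein: albumin
provenance: literature PK and induction potency
absorption:
  model: first_order
  ka: 0.6
  fa: 0.95
  fu_gut: 1.0
  qgut: 14.0
distribution:
  vss: 3.0
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 9.0
  cl_renal: 0.0
  fm_map: {}
induction:
  - {target: CYP3A4, ind_max: 2.2, ind_c50: 0.06, hill: 1.0, group: default}
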