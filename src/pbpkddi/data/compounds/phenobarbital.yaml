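# Phenobarbital: moderate CYP3A4 inducer (index perpetrator).
name: phenobarbital
mw: 232.2
logp: 1.5
compound_class: monoprotic acid
pka: 7.3
bp_ratio: 0.86
fu_plasma: 0.5
binding_protein: albumin
provenance: literature PK and induction potency
absorption:
  model: first_order
  ka: 1.0
  fa: 0.99
  fu_gut: 1.0
  qgut: 15.0
distribution:
  vss: 0.7
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 0.26
  cl_renal: 0.06
  fm_map: {}
induction:
  - {target: CYP3A4, ind_max: 1.7, ind_c50: 40.0, hill: 1.0, group: default}
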