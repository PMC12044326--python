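# Carbamazepine: moderate-to-strong CYP3A4 inducer (index perpetrator).
name: carbamazepine
mw: 236.3
logp: 2.5
compound_class: neutral
bp_ratio: 1.07
fu_plasma: 0.25
binding_protein: albumin
provenance: literature PK and induction potency
absorption:
  model: first_order
  ka: 0.5
  fa: 0.98
  fu_gut: 1.0
  qgut: 15.0
distribution:
  vss: 1.0
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 4.0
  cl_renal: 0.1
  fm_map:
    CYP3A4: 0.6
induction:
  - {target: CYP3A4, ind_max: 4.0, ind_c50: 15.0, hill: 1.0, group: default}
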