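# Midazolam: sensitive CYP3A4 probe substrate (fm,CYP3A4 ~0.94).  The
# intestinal CYP3A4 scalar pins the gut availability at the literature
# consensus FG ~0.55 for this substrate.
name: midazolam
mw: 325.8
logp: 3.5
compound_class: monoprotic base
pka: 6.0
bp_ratio: 0.66
fu_plasma: 0.032
binding_protein: albumin
provenance: literature PK; hepatic CLu_int derived retrogradely from IV clearance
absorption:
  model: first_order
  ka: 3.0
  fa: 0.96
  fu_gut: 1.0
  qgut: 14.0
distribution:
  vss: 1.0
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 27.0
  cl_renal: 0.0
  fm_map:
    CYP3A4: 0.94
  tissue_scalars:
    CYP3A4: {intestine: 0.59}
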