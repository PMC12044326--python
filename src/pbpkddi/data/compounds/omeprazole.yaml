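# Omeprazole: sensitive CYP2C19 probe substrate with a CYP3A4 share.
name: omeprazole
mw: 345.4
logp: 2.2
compound_class: ampholyte
pka: 4.8
bp_ratio: 0.59
fu_plasma: 0.045
binding_protein: albumin
provenance: literature PK; intestinal CYP3A4 scalar kept small (FG ~0.96)
absorption:
  model: first_order
  ka: 2.0
  fa: 0.95
  fu_gut: 1.0
  qgut: 14.0
distribution:
  vss: 0.3
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 30.0
  cl_renal: 0.0
  fm_map:
    CYP2C19: 0.75
    CYP3A4: 0.25
  tissue_scalars:
    CYP3A4: {intestine: 0.05}
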