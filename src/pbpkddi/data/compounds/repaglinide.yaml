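# Repaglinide: sensitive CYP2C8 probe substrate with a minor CYP3A4 share.
# The intestinal CYP3A4 scalar is set so the gut availability is ~0.9,
# matching the small first-pass gut extraction reported for this
# high-permeability substrate.
name: repaglinide
mw: 452.6
logp: 3.97
compound_class: ampholyte
pka: 4.2
bp_ratio: 0.62
fu_plasma: 0.015
binding_protein: albumin
provenance: literature PK; intestinal CYP3A4 scalar set to FG ~0.9
absorption:
  model: first_order
  ka: 2.0
  fa: 0.95
  fu_gut: 1.0
  qgut: 13.0
distribution:
  vss: 0.4
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 33.0
  cl_renal: 0.0
  fm_map:
    CYP2C8: 0.55
    CYP3A4: 0.25
  tissue_scalars:
    CYP3A4: {intestine: 0.13}
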