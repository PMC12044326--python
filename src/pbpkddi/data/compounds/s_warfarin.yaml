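# S-warfarin: sensitive CYP2C9 probe substrate (low clearance, small Vss,
# negligible gut extraction).
name: s_warfarin
mw: 308.3
logp: 2.7
compound_class: monoprotic acid
pka: 5.0
bp_ratio: 0.567
fu_plasma: 0.008
binding_protein: albumin
provenance: literature PK
absorption:
  model: first_order
  ka: 1.5
  fa: 0.99
  fu_gut: 1.0
  qgut: 15.0
distribution:
  vss: 0.14
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 0.2
  cl_renal: 0.0
  fm_map:
    CYP2C9: 0.91
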