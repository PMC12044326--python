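# Digoxin: sensitive P-gp probe substrate.  Absorption is limited by apical
# efflux out of the enterocyte (cl_efflux vs villous uptake), which is the
# site of the P-gp interaction; clearance is predominantly renal.
name: digoxin
mw: 780.9
logp: 1.26
compound_class: neutral
bp_ratio: 1.07
fu_plasma: 0.75
binding_protein: albumin
provenance: literature PK; efflux clearance set to net absorbed fraction ~0.75
absorption:
  model: first_order
  ka: 1.0
  fa: 0.95
  fu_gut: 1.0
  qgut: 12.0
  efflux: {target: P-gp, cl_efflux: 5.5}
distribution:
  vss: 7.0
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 9.5
  cl_renal: 6.5
  fm_map:
    CYP3A4: 0.2
  tissue_scalars:
    CYP3A4: {intestine: 0.0}
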