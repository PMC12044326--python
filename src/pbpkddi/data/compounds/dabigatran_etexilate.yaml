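# Dabigatran etexilate: sensitive P-gp probe substrate (prodrug).  The very
# low oral availability is dominated by apical efflux; systemic disposition
# is a simplified surrogate for the active moiety.
name: dabigatran_etexilate
mw: 627.7
logp: 3.8
compound_class: monoprotic base
pka: 6.7
bp_ratio: 0.65
fu_plasma: 0.35
binding_protein: albumin
provenance: simplified literature PK; efflux clearance set to F ~0.07
absorption:
  model: first_order
  ka: 1.0
  fa: 0.9
  fu_gut: 1.0
  qgut: 15.0
  efflux: {target: P-gp, cl_efflux: 160.0}
distribution:
  vss: 1.0
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 9.0
  cl_renal: 7.0
  fm_map: {}
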