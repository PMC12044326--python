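# Mefenamic acid: potent in-vitro UGT1A9 inhibitor.  Included as a
# no-effect regression for the victim (its target isoform carries only a
# small share of the victim's clearance and the unbound exposure is low);
# full PK fidelity is not attempted.
name: mefenamic_acid
mw: 241.3
logp: 5.1
compound_class: monoprotic acid
pka: 4.2
bp_ratio: 0.55
fu_plasma: 0.02
binding_protein: albumin
provenance: literature PK; UGT1A9 Ki from in-vitro reports
absorption:
  model: first_order
  ka: 1.2
  fa: 0.9
  fu_gut: 1.0
  qgut: 14.0
distribution:
  vss: 1.1
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 5.0
  cl_renal: 0.1
  fm_map: {}
interaction:
  ki_map:
    UGT1A9: 0.3
  fu_mic_map:
    UGT1A9: 1.0
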