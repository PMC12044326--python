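# Fluconazole: moderate competitive CYP3A4 inhibitor (index perpetrator).
# Renally cleared, low binding; Ki,u ~10 uM from in-vitro reports, giving a
# moderate oral-midazolam interaction consistent with the clinical ~2-4-fold
# range at 200 mg QD.
name: fluconazole
mw: 306.3
logp: 0.5
compound_class: neutral
bp_ratio: 1.0
fu_plasma: 0.89
binding_protein: albumin
provenance: literature PK; Ki from in-vitro inhibition reports
absorption:
  model: first_order
  ka: 1.5
  fa: 0.97
  fu_gut: 1.0
  qgut: 15.0
distribution:
  vss: 0.7
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 1.2
  cl_renal: 0.9
  fm_map: {}
interaction:
  ki_map:
    CYP3A4: 10.0
  fu_mic_map:
    CYP3A4: 1.0
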