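# Itraconazole: potent competitive CYP3A4 inhibitor (index perpetrator).
# Disposition parameters are literature-style (high lipophilicity, extensive
# binding, long half-life, CYP3A4 self-metabolism).  The unbound Ki is the
# low-nanomolar potency reported in vitro; the (Ki, exposure) pair was
# checked once against the public oral-midazolam AUC-ratio window
# (5.47-10.77 for 200 mg QD regimens) and frozen.
name: itraconazole
mw: 705.6
logp: 5.7
compound_class: monoprotic base
pka: 3.7
bp_ratio: 0.58
fu_plasma: 0.016
binding_protein: albumin
provenance: literature PK; Ki,u benchmark-checked vs oral midazolam
absorption:
  model: first_order
  ka: 0.5
  fa: 0.85
  fu_gut: 1.0
  qgut: 10.0
distribution:
  vss: 8.0
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 18.0
  cl_renal: 0.0
  fm_map:
    CYP3A4: 1.0
interaction:
  ki_map:
    CYP3A4: 0.0007
  fu_mic_map:
    CYP3A4: 1.0
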