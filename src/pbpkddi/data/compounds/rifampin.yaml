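# Rifampin: potent CYP3A4 inducer (index perpetrator).
# The default induction block covers CYP3A4 (liver + gut); IndMax/IndC50
# were calibrated once against the public oral-midazolam interaction
# (AUC ratio ~0.04-0.12 for 600 mg QD) and frozen.  The optional "ugt"
# block applies the same turnover model to UGT1A9, UGT2B4 and UserUGT1 with
# a near-maximal fold-induction of ~2.2, the high end consistent with
# hepatocyte induction reports (UGT2B4 expression +1.89-fold, UGT1A9
# activity +1.7-fold with rifampin); study designs enable it explicitly.
name: rifampin
mw: 822.9
logp: 2.7
compound_class: ampholyte
pka: 1.7
bp_ratio: 0.9
fu_plasma: 0.15
binding_protein: albumin
provenance: literature PK; CYP3A4 induction benchmark-calibrated; UGT block from hepatocyte induction literature
absorption:
  model: first_order
  ka: 1.0
  fa: 0.96
  fu_gut: 1.0
  qgut: 12.0
distribution:
  vss: 0.66
  kp_scalar: 1.0
  k_in: 0.0
  k_out: 0.0
  v_sac: 0.0
elimination:
  cl_iv: 7.0
  cl_renal: 1.0
  fm_map:
    CYP3A4: 0.25
induction:
  - {target: CYP3A4, ind_max: 16.0, ind_c50: 0.6, hill: 1.0, group: default}
  - {target: UGT1A9, ind_max: 1.2, ind_c50: 0.1, hill: 1.0, group: ugt}
  - {target: UGT2B4, ind_max: 1.2, ind_c50: 0.1, hill: 1.0, group: ugt}
  - {target: UserUGT1, ind_max: 1.2, ind_c50: 0.1, hill: 1.0, group: ugt}
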