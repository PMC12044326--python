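# Soticlestat (TAK-935): reference victim compound.
# All parameters except kp_liver are the published final model inputs for
# this compound (physicochemistry, binding, first-order absorption with
# Qgut, minimal-PBPK distribution with SAC, per-isoform elimination with
# saturable UGT kinetics, and competitive-inhibition constants).  kp_liver
# (liver:blood partition of the explicit liver compartment) is not part of
# the published set; it was fixed once at 3.5, a plausible moderate-base
# value, to reproduce the published Cmax/AUC proportion, and frozen.  The
# other open quantity (intestinal UserUGT1 abundance) lives in the system
# file.
name: soticlestat
mw: 373.45
logp: 1.4
compound_class: monoprotic base
pka: 3.37
bp_ratio: 0.6866
fu_plasma: 0.066
binding_protein: AAG
provenance: published final input parameter set, used verbatim
absorption:
  model: first_order
  papp_caco2: 23.4
  calibrators:
    - {name: atenolol, papp: 0.542}
    - {name: propranolol, papp: 27.8}
  peff_man: 3.76
  ka: 1.2
  fa: 0.98
  fu_gut: 1.0
  qgut: 2.5
distribution:
  vss: 0.36
  kp_scalar: 1.091
  kp_liver: 3.5

  k_in: 0.219
  k_out: 0.216
  v_sac: 0.234
elimination:
  cl_iv: 28.7
  cl_renal: 0.22
  fm_map:
    UGT2B4: 0.8
    UGT1A9: 0.1
    CYP3A4: 0.1
  linear_clint_map:
    CYP3A4: 0.161
  mm_map:
    UGT2B4: {vmax: 20.345, km: 5.0}
    UGT1A9: {vmax: 2.78, km: 5.0}
    UserUGT1: {vmax: 150.0, km: 5.0}
  tissue_scalars:
    UserUGT1: {liver: 0.0, intestine: 1.0, kidney: 0.0}
interaction:
  ki_map:
    CYP2C8: 14.5
    CYP2C9: 15.6
    CYP2C19: 9.5
    CYP3A4: 12.4
    P-gp: 80.0
  fu_mic_map:
    CYP2C8: 0.98
    CYP2C9: 0.88
    CYP2C19: 0.88
    CYP3A4: 0.94
    P-gp: 1.0
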