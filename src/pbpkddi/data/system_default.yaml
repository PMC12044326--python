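# Default healthy-adult system / population parameter file.
#
# These are editable population means for a generic North-European-style
# healthy adult; they do not claim to replicate any proprietary simulator
# population, only the published structure of such files.  Provenance:
#   liver weight 1650 g, MPPGL 40 mg/g      - Barter et al. 2007 (meta-analysis)
#   hepatic blood flow 97 L/h (~1.6 L/min)  - Davies & Morris 1993
#   villous mucosal flow 18 L/h (0.3 L/min) - Yang et al. 2007 (Qgut model)
#   renal blood flow 73 L/h, GFR 7.2 L/h    - Davies & Morris 1993
#   kidney 310 g, MPPGK 12.8 mg/g           - Scotcher et al. 2017
#   SI radius 1.75 cm, transit 3.32 h       - compartmental-transit literature
#   gut CYP3A4 110 nmol                     - high side of the reported
#                                             inter-individual range (mean
#                                             ~70 nmol, span ~30-160 nmol);
#                                             fixed once against the
#                                             itraconazole-midazolam
#                                             benchmark window
#   CYP turnover ~36 h half-life            - reported hepatic CYP3A4 kdeg;
#                                             applied to UGTs for want of data
#   jejunal Peff anchors (1e-4 cm/s): atenolol 0.2, propranolol 4.33
#                                           - Lennernas perfusion data /
#                                             permeability calibration sets
# Liver abundances of UGT2B4, UGT1A9 and CYP3A4 are CALIBRATED (one-time) so
# that the forward well-stirred clearance computed with the per-isoform
# intrinsic clearances of the reference compound reproduces its observed
# systemic clearance; they sit inside reported quantitative-proteomics
# ranges.  The UserUGT1 gut pool is the single oral-availability calibration
# knob (see docs/methods.md).  Abundances for isoforms this package's
# compounds never draw on are nominal literature round numbers.
provenance: see header comments
body_weight: 70.0
liver_weight: 1650.0
mppgl: 40.0
kidney_weight: 310.0
mppgk: 12.8
q_hepatic: 97.0
q_villous: 18.0
q_kidney: 73.0
enterocyte_volume: 0.3
small_intestine_radius: 1.75
small_intestine_transit: 3.32
gfr: 7.2
abundance:
  CYP1A2: {liver: 52.0, gut: 0.0, kidney: 0.0}
  CYP2B6: {liver: 17.0, gut: 0.0, kidney: 0.0}
  CYP2C8: {liver: 24.0, gut: 0.0, kidney: 0.0}
  CYP2C9: {liver: 73.0, gut: 9400.0, kidney: 0.0}
  CYP2C19: {liver: 14.0, gut: 1000.0, kidney: 0.0}
  CYP2D6: {liver: 8.0, gut: 700.0, kidney: 0.0}
  CYP3A4: {liver: 114.2, gut: 110000.0, kidney: 0.0}
  UGT1A1: {liver: 31.0, gut: 6000.0, kidney: 0.0}
  UGT1A9: {liver: 33.1, gut: 0.0, kidney: 14.0}
  UGT2B4: {liver: 36.2, gut: 0.0, kidney: 7.0}
  UserUGT1: {liver: 0.0, gut: 2916.0, kidney: 0.0}
kdeg:
  CYP1A2: 0.018
  CYP2B6: 0.022
  CYP2C8: 0.030
  CYP2C9: 0.007
  CYP2C19: 0.027
  CYP2D6: 0.014
  CYP3A4: 0.0193
  UGT1A1: 0.0193
  UGT1A9: 0.0193
  UGT2B4: 0.0193
  UserUGT1: 0.0193
peff_reference:
  atenolol: 0.2
  propranolol: 4.33
# Between-subject lognormal coefficients of variation (implementation
# defaults; the source study does not print variability magnitudes).
cv:
  body_weight: 0.14
  liver_weight: 0.15
  kidney_weight: 0.15
  enterocyte_volume: 0.10
  mppgl: 0.30
  mppgk: 0.30
  q_hepatic: 0.12
  q_villous: 0.12
  q_kidney: 0.12
  gfr: 0.15
  abundance: 0.35
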