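# Methods

`pbpkddi` simulates the pharmacokinetics and drug–drug-interaction (DDI)
liability of soticlestat, a cholesterol 24-hydroxylase inhibitor cleared
predominantly by UGT2B4/UGT1A9 glucuronidation with a minor CYP3A4 share,
in virtual healthy-volunteer trials.  This note describes the model, its
assumptions, the calibrated quantities, and what the packaged synthetic
populations can and cannot show about real data.

## Model structure

Each drug is represented by a minimal physiologically based model with an
explicit gut–liver unit (amounts in mg):

```
lumen --ka·fa--> enterocyte --Q_villi·FG(t)--> liver <--Q_H--> central <--> SAC
                      |--Q_villi·(1-FG(t))--> gut metabolite      |--> CL_R, CL_kid
                      |--cl_efflux·f_Pgp(t)--> feces
```

* **Absorption** is first order.  Human jejunal permeability is predicted
  from Caco-2 Papp by log–log regression through two calibrators (atenolol,
  the low-permeability anchor at Peff 0.2×10⁻⁴ cm/s; propranolol, the high
  anchor at 4.33×10⁻⁴ cm/s); ka = 2·Peff/R and fa follows the
  seven-compartment small-intestine transit closed form
  fa = 1 − (1 + ka·T_SI/7)⁻⁷.  Explicit file values (ka 1.2 h⁻¹, fa 0.98
  for the victim) override predictions.
* **Gut first pass** applies the Qgut availability
  FG = Qgut/(Qgut + fu_gut·CLu_int,gut) to the absorbed flux as it leaves
  the enterocyte.  Per-isoform gut intrinsic clearances are *linear*
  (Vmax/Km for the saturable UGTs).  Evaluating gut Michaelis–Menten
  kinetics at the raw Qgut-model enterocyte concentration (hundreds of µM
  at a 300 mg dose) would saturate gut UGT completely and make the observed
  oral availability (~0.16) unreachable; the dose-nonlinearity is carried
  by the liver instead (below).  FG is recomputed continuously from the
  net inhibition×induction factor of each intestinal isoform, which is how
  gut DDIs act on the victim.
* **Liver** is an explicit well-stirred compartment (volume = liver
  weight × Kp_liver × Kp scalar, blood-referenced).  Hepatic metabolism
  runs at the unbound liver concentration Cu = fu_b·C_liver: saturable UGT
  pathways as Vmax·Cu/(Km + Cu) with the unbound Km of 5 µM, CYP3A4 and the
  "other" (uninhibitable) pathway as linear CLu_int·Cu.  Because portal
  inflow raises liver concentrations during absorption, UGT saturation
  produces the greater-than-dose-proportional AUC the compound shows — and
  a small positive feedback under CYP3A inhibition.
* **Distribution** is the minimal-PBPK convention: a central compartment
  plus a single adjusting compartment (SAC).  SAC influx is
  k_in·V_SAC·C_plasma and efflux k_out·A_SAC, the only reading under which
  the published set (Vss 0.36, V_SAC 0.234 L/kg, k_in 0.219, k_out
  0.216 h⁻¹) is internally consistent; the central volume is derived as
  Vc = Vss·BW − V_SAC·BW·k_in/k_out − V_liver,app·B:P.
* **Renal elimination**: the observed excretory CL_R (0.22 L/h, scaled with
  GFR) plus a small renal *metabolic* clearance from the kidney UGT1A9 and
  UGT2B4 pools (well-stirred against renal blood flow), consistent with the
  retrograde treatment of the in-vivo clearance.
* **Interactions.**  Competitive inhibition multiplies each isoform's
  CLu_int by 1/(1 + Cu/Ki,u) with Ki,u = Ki·fu_mic.  Induction is a
  turnover model dE/dt = kdeg·(E0·(1 + IndMax·Cuʰ/(IndC50ʰ + Cuʰ)) − E) per
  enzyme × tissue (liver and gut).  Hepatic interactions are driven by the
  perpetrator's unbound liver concentration; gut interactions by its
  unbound enterocyte pool.
* **P-gp** is modeled on the substrate side as an apical efflux clearance
  out of the enterocyte competing with villous-blood uptake; the
  perpetrator inhibits that efflux term (Ki 80 µM for soticlestat) through
  its enterocyte unbound concentration.  Effluxed drug is treated as not
  reabsorbed.

### The enterocyte interaction pool

The concentration that drives gut inhibition/induction is a deliberate
structural choice, because the literature offers a 100-fold range: the
conservative static convention I_gut = fa·ka·Dose/Qgut gives ~400 µM for a
300 mg victim dose, while the systemic unbound concentration gives
~0.03 µM.  Here the enterocyte pool is the absorption flux transiting a
compartment turned over by villous mucosal blood flow (18 L/h), carrying
the *blood* unbound fraction, plus the arterial unbound term — peak ~5 µM
for this compound.  This sits between the two conventions and treats
intracellular binding as mirroring blood binding.  It makes gut DDI
predictions moderate rather than worst-case; a user wanting the
conservative regulatory screen should use `ddi_static`, which applies
dose/250 mL to the gut.

### Retrograde clearance derivation

For compounds parameterized by an in-vivo clearance, the whole-body
metabolic blood clearance (CL_IV − CL_R)/B:P is inverted through the
well-stirred model (liver + kidney coupled through shared per-pmol values)
by a bracketing root solve; the hepatic pool splits across isoforms in
proportion to fm.  The inversion is exact to 1e-8 and reproduces the
published per-pmol values (4.069 / 0.556 / 0.161 µL/min/pmol) given the
packaged abundances.  fm values are interpreted as fractions of the
*non-renal* clearance, with CL_R purely excretory.

## System file and calibrated quantities

Physiology defaults (liver 1650 g, MPPGL 40 mg/g, Q_H 97 L/h, Q_villi
18 L/h, kidney 310 g at 12.8 mg/g, Q_K 73 L/h, GFR 7.2 L/h) are standard
literature values recorded with provenance in the system file.  Five
quantities could not be taken from any table and were calibrated **once**,
then frozen:

| quantity | value | anchor |
|---|---|---|
| liver abundances UGT2B4/UGT1A9/CYP3A4 | 36.2 / 33.1 / 114.2 pmol/mg | forward clearance must equal CL_IV − CL_R with the published per-pmol CLu_ints |
| gut CYP3A4 pool | 110 nmol | itraconazole–midazolam AUC-ratio window 5.47–10.77 (high side of the reported 30–160 nmol inter-individual range) |
| gut UserUGT1 pool | 2916 pmol | victim oral AUC (single 300 mg) = 1688 h·ng/mL; total victim gut CLu_int 6.31 L/h |
| victim Kp_liver | 3.5 | Cmax/AUC proportion of the published single-dose exposure (AUC is insensitive to it) |
| rifampin CYP3A4 IndMax/IndC50 | 16 / 0.6 µM | clinical oral-midazolam AUC ratio ~0.04–0.12 at 600 mg QD |

The rifampin UGT block (IndMax 1.2, i.e. maximal fold ~2.2, on UGT1A9,
UGT2B4 and UserUGT1, enabled by the `ugt` study-design flag) is anchored to
hepatocyte induction reports (UGT2B4 expression +1.89-fold, UGT1A9 activity
+1.7-fold under rifampin), taken at the high end; the resulting comparison
is a calibrated, not parameter-free, reproduction.  Likewise the probe
substrates' intestinal CYP3A4 scalars pin their gut availabilities at
literature consensus values (midazolam FG ≈ 0.55, repaglinide ≈ 0.9,
omeprazole ≈ 0.96).

## Virtual populations

Demographics follow the simulated trial conditions: n subjects aged 20–50,
an exact 50% female split, sex-specific lognormal body weight (GM 66/78 kg,
CV 14%).  Organ sizes scale linearly with weight and flows with weight^0.75;
abundances, microsomal scaling and flows get independent lognormal
between-subject variability whose CVs (e.g. 35% on abundances) are
implementation defaults recorded in the system file — the source
simulations do not print variability magnitudes, so confidence-interval
widths are illustrative, not reproductions.  Sampling preserves nominal
values as geometric means and is bit-reproducible under a seed.

DDI contrasts are within-subject: both arms reuse the same individuals,
which is what makes 90% CIs as tight as the published ones possible and
makes the GMR against an interaction-free co-drug exactly 1.

## Trial statistics

NCA uses the linear-up/log-down trapezoid; λz comes from the best
adjusted-R² log-linear fit over the last 3–8 post-Cmax points;
AUC0-inf = AUC0-t + C_last/λz.  Samples below 10⁻⁶×Cmax are treated as
below the quantification floor (they are integrator noise).  GMRs are
exp(mean log ratio) with a t-based 90% CI.

## Numerics

LSODA with rtol 1e-8 / atol 1e-10 (mg scale), integrated segment-wise
between dose events; oral doses enter the lumen as impulses.  Mass balance
is checked to 0.1% per drug per run (typically ~1e-12), and halving the
tolerances moves AUC by <0.01%.  Output grids are dense (0.1 h) after the
victim's final dose and sparse (2 h) during perpetrator lead-in.  When the
co-administered drug has no interaction surface the two drugs are
integrated separately, which decouples them exactly.

## Problem sizes

The pytest acceptance layer runs every study at n=40 (within-subject GMR
point estimates move by <1% between n=40 and n=100);
`scripts/acceptance.py` reruns everything at the reported scale, n=100.

## Limitations

* The secondary absorption peak (enterohepatic recirculation) is not
  modeled, matching the scope of the reference parameterization; absolute
  Tmax and late-phase shape are therefore approximate.
* No mechanism-based (time-dependent) CYP inhibition — the victim shows
  none in vitro — and no transporter interactions beyond intestinal P-gp.
* Perpetrator PK models are deliberately coarse (mostly one-compartment,
  no autoinduction for rifampin/carbamazepine); they are calibrated to
  deliver realistic *interaction pressure* at the studied regimens, not to
  reproduce their own exposure profiles.
* The population is a structural stand-in for the commercial simulator's
  proprietary healthy-volunteer population; between-subject CVs, and hence
  CI widths and population extremes, are illustrative.
* Passing the packaged checks shows the model reproduces the published
  *simulated* quantities under these study conditions; it does not validate
  predictions outside them (other doses, populations, or perpetrators).
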