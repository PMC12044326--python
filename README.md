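# pbpkddi

Minimal physiologically based pharmacokinetic (PBPK) simulation of
**soticlestat** — a cholesterol 24-hydroxylase inhibitor in development for
developmental epileptic encephalopathies — and of its drug–drug-interaction
(DDI) liability, both as a **victim** of CYP3A inhibition/induction (and
hypothesized UGT induction) and as a **perpetrator** against CYP2C8, CYP2C9,
CYP2C19, CYP3A4 and P-gp probe substrates.

The package is aimed at modelers who want an open, testable implementation
of the mechanistic-DDI workflow that commercial population simulators
provide: compound files, virtual healthy-volunteer populations,
a dynamic victim+perpetrator engine, non-compartmental analysis and trial
statistics.

## The model in brief

Each drug follows a minimal PBPK topology — gut lumen → enterocyte →
explicit well-stirred liver ↔ central compartment ↔ single adjusting
compartment (SAC) — with:

* first-order absorption (ka, fa predicted from Caco-2 permeability or set
  explicitly) and Qgut intestinal first-pass availability
  FG = Q_gut/(Q_gut + fu_gut·CLu_int,gut);
* well-stirred hepatic clearance CL = Q_H·fu_B·CLu_int/(Q_H + fu_B·CLu_int),
  with per-isoform unbound intrinsic clearances obtained either from
  Vmax/Km (saturable UGT2B4, UGT1A9 and an intestinal "User UGT"
  glucuronidation pathway, Km 5 µM unbound) or by retrograde inversion of an
  observed in-vivo clearance split by fm;
* dynamic competitive inhibition, factor 1/(1 + Cu/K_i,u) with
  K_i,u = K_i·fu_mic, and turnover-based induction
  dE/dt = k_deg·(E₀·(1 + Ind_max·Cu/(IndC₅₀ + Cu)) − E), per enzyme in
  liver and gut;
* within-subject virtual crossover trials: geometric mean ratios (GMR) of
  Cmax and AUC₀–∞ with 90% CIs across n=100 subjects (20–50 y, 50% female).

See `docs/methods.md` for assumptions, calibrated quantities and
limitations.

## Worked example

Simulate the single-dose exposure study (here a quick n=5 run):

```bash
$ pbpkddi study soticlestat_300_single --n 5 --seed 3
{
  "ref_cmax_gm": 1084.7918158150246,
  "ref_auc_inf_gm": 1591.454893894337
}
```

That is the population geometric mean Cmax (ng/mL) and AUC₀–∞ (h·ng/mL)
after a single oral 300 mg dose — at full scale (n=100) these land around
1000–1200 ng/mL and 1450–1700 h·ng/mL depending on the population seed,
within ±30% of the published simulated values of 1242 ng/mL and
1688 h·ng/mL.

A victim DDI study returns the within-subject contrast:

```bash
$ pbpkddi study itraconazole_soticlestat --n 20 --seed 3
```

reports `auc_gmr` ≈ 1.28 with its 90% CI: 14 days of itraconazole 200 mg QD
(potent CYP3A4 inhibitor) raises soticlestat exposure by roughly a third —
a weak interaction, because CYP3A4 carries only ~10% of soticlestat
clearance.

From Python:

```python
import pbpkddi as p

lib = p.compound_library()
res = p.run_ddi_study(p.builtin_study("soticlestat_midazolam"), lib, seed=1)
print(res.gmr_auc.point)        # ~1.13: weak perpetrator effect on CYP3A4
```

Other entry points: `pbpkddi validate`, `pbpkddi derive soticlestat`
(retrograde clearance report), `pbpkddi simulate <study>` (tidy profile
CSV), `pbpkddi static <study>` (conservative mechanistic static screen),
`pbpkddi fixtures list/show`.

## Layout

| module | role |
|---|---|
| `compound_io` | compound/study YAML schemas, validation, round-trip I/O |
| `population` | system (physiology) file, virtual-population sampling |
| `absorption_clearance` | Peff/ka/fa prediction, well-stirred model, MM kinetics, Qgut, retrograde derivation |
| `pbpk_engine` | coupled victim+perpetrator ODE integration |
| `ddi_static` | basic R-values, mechanistic static AUCR, Ki,u sensitivity scan |
| `trial_stats` | NCA, GMR statistics, study orchestration |
| `fixtures` | packaged compound/study library, synthetic-profile generators |
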