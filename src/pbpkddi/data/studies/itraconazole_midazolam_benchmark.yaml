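name: itraconazole_midazolam_benchmark
victim:
  compound: midazolam
  dose_mg: 5.0
  route: oral
  regimen:
    interval_h: 24.0
    n_doses: 1
  sampling_duration_h: 48.0
perpetrator:
  compound: itraconazole
  dose_mg: 200.0
  route: oral
  regimen:
    interval_h: 24.0
    n_doses: 7
  lead_in_days: 4.0
  victim_dose_day: 4.0
population:
  n: 12
  age_range:
  - 20.0
  - 50.0
  prop_female: 0.5
  seed: 7
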