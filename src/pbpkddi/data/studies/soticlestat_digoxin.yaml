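name: soticlestat_digoxin
victim:
  compound: digoxin
  dose_mg: 0.5
  route: oral
  regimen:
    interval_h: 24.0
    n_doses: 1
  sampling_duration_h: 144.0
perpetrator:
  compound: soticlestat
  dose_mg: 300.0
  route: oral
  regimen:
    interval_h: 12.0
    n_doses: 27
  lead_in_days: 7.0
  victim_dose_day: 7.0
population:
  n: 100
  age_range:
  - 20.0
  - 50.0
  prop_female: 0.5
  seed: 1234
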