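constraints:
  blood_volume_tolerance: 0.1
  co:
  - 4.0
  - 8.0
  ef:
  - 50.0
  - 75.0
  gfr:
  - 85.0
  - 125.0
  hct:
  - 0.37
  - 0.49
  hr:
  - 60.0
  - 90.0
  k0:
  - 0.2
  - 0.8
  lvedp:
  - 3.0
  - 12.0
  phi_sod_in:
  - 0.028
  - 0.2088
  rbf:
  - 900.0
  - 1300.0
  svr:
  - 700.0
  - 1600.0
n_patients: 50
output_dir: runs
sampling:
  bmi_mean: 29.0
  bmi_sd: 5.0
  dbp_mean: 100.0
  dbp_sd: 10.0
  height_max: 180.0
  height_min: 160.0
  hr_mean: 75.0
  hr_sd: 10.0
  male_fraction: 0.5
  sbp_mean: 160.0
  sbp_sd: 10.0
  weight_mean: 80.0
  weight_sd: 20.0
seed: 0
treatment_duration_s: 2419200.0
verbosity: 1
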