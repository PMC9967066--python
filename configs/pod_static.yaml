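# Static-chamber pod run: 20 puffs, 3 min apart, unimodal 100 nm source.
# Run with:  puffbox run --config configs/pod_static.yaml --out results/pod_static
seed: 7
scenario:
  volume_Vc_m3: 6.0
  ach: 0.0
  label: static
schedule:
  n_puffs: 20
  interval_s: 180.0
  start_s: 60.0
  profile: {volume_mL: 55.0, duration_s: 3.0}
source:
  number_per_puff: 4.92e+10
  modes:
    - {weight: 1.0, gmd_nm: 100.0, gsd: 1.7}
simulation:
  beta_dep_per_s: 1.34e-4
  dt_s: 10.0
  t_end_s: 10680.0
  noise: {gsd: 1.05, poisson: false}
instrument:
  ops_ceiling_per_cm3: 3000.0
device:
  device_type: pod
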