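# Demo: small synthetic megacity domain, all five stages.
# Run:  greenozone run-all --config examples/demo_config.yaml
seed: 1
outdir: scratch/demo_run
synthetic:
  domain_size_km: 30.0
  coarse_res_km: 1.0
  fine_res_m: 50.0
  n_days: 20            # retained analysis days
  spinup_days: 4        # dropped at load
  urban_radius_km: 9.0
  urban_green_fraction: 0.35
  delta_o3_urban_ppb: 3.6
  temp_coupling: 0.08
  pop_total: 2.0e7
  incidence_annual: 9.0e-4
health:
  rr_per_10ppb: 1.06
  c0: 32.4
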