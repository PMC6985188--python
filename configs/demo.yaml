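# Demo: a small synthetic cohort across the three standard well diameters.
# Run:  wellquant quantify --config configs/demo.yaml
mode: synthetic
seed: 1
replicates: 4                 # 4 wells per diameter -> 12 wells
diameters_um: [150.0, 300.0, 500.0]
output_dir: demo_out
well_overrides:
  noise_sd: 5.0
  min_separation: 1.1
quant:
  n_zones: 4
  contrast_threshold: 1.25
  flatness_cv: 0.15
tolerances:                   # used by `wellquant validate`
  count_error: 1
  nc_rel_err: 0.05
  actin_accuracy: 0.95
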