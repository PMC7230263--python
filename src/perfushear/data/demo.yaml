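# Demo run: small acquisition grid so the whole pipeline finishes in seconds.
master_seed: 0
output_dir: perfushear_run
log_level: INFO

synth:
  scene:
    tile_size: 256
    grid_rows: 2
    grid_cols: 3
    z_planes: 4
    nodule_count: 12
    area_min_um2: 900.0
    area_max_um2: 6000.0
  doses: [0, 500]
  survival_fractions: [1.0, 0.18]
  replicates: 2
  replicate_cv: 0.05

quant:
  cutoff_um2: 2000
  sweep_cutoffs_um2: [500, 1000, 1500, 2000, 2500, 3000]

fluids:
  a_values_um: [40, 100]
  porous: both
  cell_size_um: 4.0
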