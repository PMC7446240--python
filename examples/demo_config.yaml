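# Demo configuration for the end-to-end pipeline runner.
# Run with:  python examples/05_pipeline.py
seed: 11
out_dir: scratch/pipeline_demo
n_conditions: 8
geometry_dims: 5
stages:
  glove_model:
    n_runs: 1
    trials_per_block: 2
  ethological_model: {}
  searchlight:
    subdivisions: 1
    radius_mm: 12.0
    patch_radius_mm: 10.0
    n_runs: 3
    diameter_mm: 14.0
    n_perm: 200
    block_s: 8.0
  temporal:
    n_sources: 8
    fs: 200.0
    trials_per_condition: 10
    n_partitions: 5
    n_perm: 200
    fwe_alpha: 0.01
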