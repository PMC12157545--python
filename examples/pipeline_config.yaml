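# Demo configuration for `cstract pipeline --config examples/pipeline_config.yaml`.
# Runs the full two-species analysis (phantoms -> 23-tract library + reference
# tracts -> blueprints -> homologue report) in well under a minute on one CPU.
rng_seed: 0
seeds_per_voxel: 40
out_dir: pipeline_demo_out
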