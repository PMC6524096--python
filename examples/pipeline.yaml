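# Full-pipeline configuration: simulate a default-design study and run
# every stage. Swap the `simulate` block for an `inputs` block
# (counts/metadata/taxonomy/tree paths, optional format: biom-json)
# to analyse real data.
out_dir: scratch/pipeline_out
seed: 1
simulate:
  n_per_cell: 10
  n_otus: 300
rarefaction_depth: auto
thresholds:
  prevalence: 0.75
  abundance: 0.01
  rho: 0.7
  p: 2.32e-5
  pathway: 0.333
permutations: 999
reference_age: 49
maturity_metric: bray
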