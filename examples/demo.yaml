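# Self-contained demo run: two castes, queen with a 4x structural load.
# termipep all -c examples/demo.yaml -o demo-run
seed: 1
catalog:
  n_neuropeptides: 2
  n_proteins: 0
  n_household: 3
simulate:
  castes:
    worker: {structural_load: 1.0}
    queen: {structural_load: 4.0}
  replicates: 3
  n_spots: 3000
  bias: 1.5
  dup_rate: 0.05
  error_rate: 0.005
normalize:
  tau: 0.25
compare:
  measure: frac
  pseudocount: 0.0
test:
  alpha: 0.05
  castes: [worker, queen]
qc:
  min_marker_spots: 2
  depth_floor: 1000
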