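# Desk-scale experiment grid: semantic ablation across topology conditions.
# Run:  kgablate grid --config examples/grid.yaml --out records.csv
#       kgablate trend records.csv
dataset_label: synthetic-default
task: drug-disease
# synthetic-generator overrides (omit the block to use the defaults,
# or set kg_path: /path/to/triples.tsv plus dataset_naming: gnbr|hetionet
# to run on a real DRKG subset)
synthetic: {}
models: [TransE]
alphas: [2.0, 0.0, -2.0]   # degree-strength of triple downsampling
ds: [1.0, 0.5, 0.25]       # fraction of triples retained
ps: [1.0]                  # hub-removal percentile (1.0 = no hub removal)
f_hubs: 1.0
modes: [control, corrupt, flatten]
seeds: [0, 1, 2, 3, 4, 5, 6, 7]
epochs: 50                 # desk scale; the full-scale protocol uses 500
test_fraction: 0.05
min_endpoint_degree: 4
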