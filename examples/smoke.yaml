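# Minimal end-to-end pipeline configuration: a tiny synthetic dataset,
# default 10/90 percentile masks, a small network, two training epochs.
#   voxhazard run examples/smoke.yaml --out runs/smoke --seed 5
data:
  synthetic: {n_train: 20, n_val: 8, n_test: 8, grid: 16, seed: 3}
mask: {lower: 10, upper: 90}
model:
  in_shape: [16, 16, 16]
  feature_size: 2
  filter_size: 3
  depth: 2
  final_layer_neurons: 4
  pooled_size: 2
train: {epochs: 2, learning_rate: 0.003, batch_size: 8, seed: 5}
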