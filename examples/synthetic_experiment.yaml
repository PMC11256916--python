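# End-to-end synthetic deconvolution experiment:
#   scgraphdec run --config examples/synthetic_experiment.yaml --out results/demo
seed: 0
synthetic:
  n_bins: 256
  n_cell_types: 2
  mixture_weights: [0.6, 0.4]
  read_depth_bulk: 5.0e+5
  read_depth_sc: 5.0e+4
  expr_coupling: 0.9
  noise_sd: 0.05
  train_chroms: [s1, s2, s3]
  test_chroms: [s4]
model:
  d_model: 48
  n_attention_heads: 4
  pe_k: 16
train:
  epochs: 50
  learning_rate: 3.0e-3
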