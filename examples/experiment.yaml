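# Desk-scale experiment configuration (see docs/methods.md for rationale).
generator:
  n_cases: 2000
  n_elements: 62
  affinity_strength: 0.8
  noise_rate: 0.1
model:
  embedding_dim: 16
  n_experts: 4
  expert_layer_sizes: [32, 16]
  tower_layer_sizes: [16]
  match_tower_sizes: [32, 16, 16]
  lambda1: 1.0
  lambda_u: 0.5
  lambda_v: 0.5
train:
  learning_rate: 0.005
  batch_size: 512
  epochs: 10
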