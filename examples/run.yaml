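# Full pipeline on the default synthetic interaction dataset.
seed: 42
out_dir: runs/demo
data:
  name: synthetic
  synth:
    n_drugs: 60
    n_targets: 40
    density: 0.05
    noise_sd: 0.1
model:
  hyper:
    epochs: 60
sso:
  enabled: true
  np: 10
  t_max: 10
  epochs: 10
eval:
  cv_seeds: [3201, 2033, 5179, 2931, 9117]
  cv_epochs: 40
  theta: 0.5
  k_grid: [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
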