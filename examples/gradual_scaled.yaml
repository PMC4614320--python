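# Scaled three-layer run: gradual 16-node lesion, disability-dependent
# learning rate.  Use with:
#   lesionlab run-three-layer --config examples/gradual_scaled.yaml --seed 0
model: three_layer
three_layer: {}          # reference defaults (N=500, n=100, ...)
eta:
  mode: modified
  eta0: 0.01
  H0: 5
  Hc: 15                 # case-dependent; scaled to the N=100 preset
lesion:
  kind: gradual
  m: 16
  irt: 50
  start_time: 1000
run:
  scale: scaled          # run at N=100, n=20
  master_seed: 0
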