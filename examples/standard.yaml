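# Standard study conditions: 100 replicate input streams, 40 rounds each,
# activation noise off, decay fixed at 0.5.
seed: 1
n_replicates: 100
simulation:
  tau: -3.14
  P: 20.0
  d: 0.5
  n_rounds: 40
  p1: 6
sweep:
  tau: [-6.0, 0.0, 1.0]
  P: [5.0, 35.0, 5.0]
optimize:
  mode: performance
  method: nelder-mead
  a: 1.0
  b: 0.0
smooth_compare:
  h_argmax: [1.0e+7, 1.0e+3]
  h_sim: 10.0
  h_env: 10.0
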