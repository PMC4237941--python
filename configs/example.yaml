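# Balanced couplet mix at its homeostatic point, perturbed by a spike of
# species "a" at step 20.  Run with:  ctc-sim run configs/example.yaml
seed: 1
steps: 240
variant: EC
binding:
  ka: 1.0e+10
initial_cells:
  A: 24
  I: 24
pool:
  volume: 1.0e-3
  total_a: 4.8e-10
  total_i: 4.8e-10
events:
  - at_step: 20
    kind: ADD_TREFONE
    species: a
    amount: 2.0e-9
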