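# End-to-end "mixed source" run: imaging volume plus a mixed
# synchronous/asynchronous evoked recording and a mini recording.
seed: 23
imaging:
  volume:
    shape_xy: [192, 192]
  population:
    count: 20
ephys:
  scenario: mixed
  n_trials: 20
  noise_sd: 2.0
  window_ms: [0.0, 500.0]
minis:
  duration: 30.0
  noise_sd: 2.0
  detector:
    deriv_k: 5.0
    integ_k: 3.0
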