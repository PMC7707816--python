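# Imaging-only run: synthetic bouton volume -> detection -> scoring -> report
seed: 11
imaging:
  volume:
    shape_xy: [256, 256]
    n_z: 15
    background_mean: 20.0
    background_sd: 4.0
  population:
    count: 40
    p_glyt2: 0.4
    p_syt12: 0.5
    min_separation_um: 2.0
  coloc:
    thresholds:
      glyt2_pos: 0.4
      glyt2_neg: 0.1
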