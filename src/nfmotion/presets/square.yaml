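# Component and pattern motion (solid 24 x 24 square): both fields trained
# on the 8 moving-square sequences, NF1 first. NF1 dim 13 / rf 12 has no
# integer-stride tiling (offsets spread evenly over 0..52); NF2's rf 13
# covers the whole 13 x 13 NF1 sheet, so all 15 x 15 neurons share the
# full-field RF.
name: square
image_size: 64
stimuli:
  kind: square
  n_frames: 5
  square_size: 24
fields:
  - dim: 13
    rf: 12
    r_exc: 3
    r_inhb: 6
    gamma_aff: 1.0
    gamma_exc: 2.8
    # inhibitory gains recalibrated for unit-sum weight normalization
    # (source table prints 1.0 / 1.5); see docs/methods.md
    gamma_inhb: 6.0
    alpha_aff: 0.3
    alpha_exc: 0.3
    alpha_inhb: 0.3
    settling_steps: 10
    epochs: 500
    settle_lo: 0.01
    settle_hi: 2.0
  - dim: 15
    rf: 13
    r_exc: 3
    r_inhb: 7
    gamma_aff: 1.0
    gamma_exc: 2.2
    gamma_inhb: 5.0
    alpha_aff: 0.3
    alpha_exc: 0.3
    alpha_inhb: 0.3
    settling_steps: 10
    epochs: 500
    settle_lo: 0.01
    settle_hi: 2.0
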