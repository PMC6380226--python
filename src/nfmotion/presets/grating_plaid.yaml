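# Component and pattern motion (gratings -> plaids): NF1 trained on the 8
# drifting gratings, NF2 on the 8 moving plaids with NF1 frozen.
# NF1 dim 20 with rf 24 has no integer-stride tiling of a 64 px image;
# RF origins are spread evenly (rounded linspace over offsets 0..40).
name: grating_plaid
image_size: 64
stimuli:
  kind: grating_plaid
  n_frames: 10
  spatial_period_px: 5
fields:
  - dim: 20
    rf: 24
    r_exc: 2
    r_inhb: 10
    gamma_aff: 1.0
    gamma_exc: 8.2
    # inhibitory gains recalibrated for unit-sum weight normalization
    # (source table prints 1.0 / 3.0); see docs/methods.md
    gamma_inhb: 8.0
    alpha_aff: 0.05
    alpha_exc: 0.05
    alpha_inhb: 0.05
    settling_steps: 10
    epochs: 1500
    settle_lo: 0.2
    settle_hi: 2.0
  - dim: 13
    rf: 8
    stride: 1
    r_exc: 3
    r_inhb: 4
    gamma_aff: 1.0
    gamma_exc: 4.8
    gamma_inhb: 8.0
    alpha_aff: 0.05
    alpha_exc: 0.05
    alpha_inhb: 0.05
    settling_steps: 8
    epochs: 500
    settle_lo: 0.05
    settle_hi: 2.0
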