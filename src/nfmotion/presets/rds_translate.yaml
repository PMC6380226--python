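# Translational flow (random-dot stimuli): NF1 afferents fixed at 1
# (position-independent drive, gamma_aff 0.3), NF2 learns with the
# asymmetric rule; a perceptron readout decodes the 4 flow directions.
# Frames are the 32 x 32 grids of the dot generator; stride 1 then
# realizes the preset dims exactly (29 = (32-4)/1+1, 22 = (29-8)/1+1).
# The parameter table's nominal "image size 16 x 16" bookkeeping is
# documented here but not used for geometry.
name: rds_translate
image_size: 32
stimuli:
  kind: rds_translate
  n_configurations: 25
  n_train_configurations: 20
  n_frames: 5
fields:
  - dim: 29
    rf: 4
    stride: 1
    r_exc: 3
    r_inhb: 4
    gamma_aff: 0.3
    gamma_exc: 0.68
    gamma_inhb: 1.0
    alpha_aff: 0.05
    alpha_exc: 0.05
    alpha_inhb: 0.05
    settling_steps: 10
    epochs: 200
    unit_afferent: true
  - dim: 22
    rf: 8
    stride: 1
    r_exc: 3
    r_inhb: 5
    gamma_aff: 1.0
    gamma_exc: 15.68
    # recalibrated (source table prints 1.0): strong surround inhibition
    # puts the field in a winner-take-all regime with incumbency
    # hysteresis, the regime in which its response carries motion order;
    # see docs/methods.md
    gamma_inhb: 14.0
    alpha_aff: 0.05
    alpha_exc: 0.05
    alpha_inhb: 0.05
    settling_steps: 10
    epochs: 200
    settle_lo: 0.2
    settle_hi: 9.0
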