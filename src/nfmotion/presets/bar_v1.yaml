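# Direction selectivity (thin moving bar), single field analogous to V1.
# Full-field receptive fields: every neuron sees the whole 64 x 64 image,
# so RF origins all sit at offset 0 (stride left unset).
name: bar_v1
image_size: 64
stimuli:
  kind: bar
  n_sequences: 8
  n_frames: 8
  bar_len: 30
  bar_width: 2
  step_px: 7.8
fields:
  - dim: 20
    rf: 64
    r_exc: 3
    r_inhb: 10
    gamma_aff: 1.0
    gamma_exc: 3.9
    # inhibitory gain recalibrated for the unit-sum weight normalization
    # (source table prints 1.0, which cannot confine activity bubbles
    # under per-type row normalization); see docs/methods.md
    gamma_inhb: 8.0
    alpha_aff: 0.05
    alpha_exc: 0.05
    alpha_inhb: 0.05
    settling_steps: 10
    epochs: 500
    # settling-sigmoid operating range (afferent drive is ~1.5e-2 with
    # full-field RFs and unit-sum weights; lateral drive is O(1))
    settle_lo: 0.01
    settle_hi: 2.0
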