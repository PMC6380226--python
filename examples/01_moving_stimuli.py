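"""Generate the synthetic moving stimuli and inspect their geometry.

Every experiment in this package runs on internally generated image
sequences: bars, step edges, drifting gratings, plaids, solid squares and
translating random-dot fields. This script builds one of each and prints
the properties the generators guarantee.
"""

import numpy as np

from nfmotion import (make_moving_bar, make_moving_edge, make_moving_grating,
                      make_moving_plaid, make_moving_square,
                      make_rds_configuration, make_rds_translation)

bar = make_moving_bar(0)  # rightward motion; the bar itself is vertical
print(f"bar: {bar.n_frames} frames of {bar.frame_shape}, "
      f"{int(bar.frames[0].sum())} lit pixels per frame (30 x 2 bar)")

edge = make_moving_edge("L2R")
print(f"edge: {edge.n_frames} frames; frame 10 has "
      f"{int(edge.frames[10][0].sum())} lit columns (one column per time step)")

grating = make_moving_grating(45, spatial_period_px=5)
rev = make_moving_grating(225)
print(f"grating: period 5 px; the 225-degree sequence is the time reversal "
      f"of the 45-degree one: {np.allclose(grating.frames, rev.frames[::-1])}")

plaid = make_moving_plaid(45)
print(f"plaid moving at 45 degrees is built from gratings moving at "
      f"{plaid.meta['component_directions']} (pattern direction +/- 45)")

square = make_moving_square(135)
print(f"square: {square.n_frames} frames, "
      f"{int(square.frames[0].sum())} lit pixels (24 x 24) in every frame")

cfg = make_rds_configuration(seed=7)
rds = make_rds_translation(cfg, 90)
print(f"random dots: {int(rds.frames[0].sum()) // 4} dots of 2x2 px on a "
      f"32 x 32 torus; density conserved across frames: "
      f"{[int(f.sum()) for f in rds.frames]}")
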