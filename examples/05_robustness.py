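"""Robustness of a trained direction map to input noise and bar length.

A bar-trained field is probed with corrupted copies of its training
stimuli. The robustness index RI = 1 - (deviated neurons / all neurons)
compares each perturbed preference map against the clean one: 1 means no
neuron changed its preferred direction.
"""

from nfmotion.experiments import run_robustness

res = run_robustness(seed=3, noise_kind="salt_pepper", n_levels=10)
curve = res["curve"]
print("salt-and-pepper noise sweep (density -> robustness index):")
for lv, ri in zip(curve.noise_levels, curve.ri):
    print(f"  density {lv:4.2f}: RI = {ri:.3f}")

lengths = res["length_curve"]
ri30 = lengths.ri[list(lengths.noise_levels).index(30.0)]
print(f"bar-length sweep: RI at the training length (30 px) = {ri30:.2f}; "
      f"range over 15-35 px = [{lengths.ri.min():.2f}, {lengths.ri.max():.2f}]")
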