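# nfmotion

A rate-based simulator of motion processing in the dorsal visual pathway.
Hierarchies of **neural fields** — 2-D sheets of neurons with retinotopic
receptive fields, short-range lateral excitation and long-range lateral
inhibition — are trained on synthetic moving stimuli with a **temporally
asymmetric Hebbian rule**, a rate analogue of spike-timing-dependent
plasticity. Out of this emerge direction-selectivity maps (V1-like),
pattern-motion selectivity over components (MT-like), and a population
code for translational optic flow (MST-like) that a linear perceptron can
read out. The package is aimed at computational-neuroscience researchers
who want a compact, fully reproducible testbed for lateral-plasticity
models of motion selectivity.

## Model

Each neuron *(i,j)* of a field computes its afferent drive from its
receptive-field patch *X·ij* through nonnegative weights *W·ij*:

    S_ij = σ( γ_aff · ⟨W_ij, X_ij⟩ )

with σ a piecewise-linear sigmoid. The sheet then settles for *Ts* steps
of lateral interaction at fixed drive,

    η_ij(s) = σ( S_ij + γ_exc Σ_kl E_ij,kl η_kl(s−1) − γ_inhb Σ_kl I_ij,kl η_kl(s−1) ),

where *E* lives on the disc d ≤ r_exc and *I* on the annulus
r_exc < d ≤ r_inhb. Settling starts from the previous frame's settled
state (zero at sequence onset), so responses carry stimulus history.
After settling, weights adapt:

    ΔW_ij,kl = α_aff · X_kl · η_ij(t)                            (afferent)
    ΔW_ij,kl = α · max(0, η_ij(t) − η_ij(t−1)) · η_kl(t−1)       (lateral, asymmetric)

followed by divisive normalization of each neuron's incoming weights per
connection type, `W ← (W + ΔW) / Σ(W + ΔW)`. A temporally symmetric
control rule (`ΔW = α η_ij(t) η_kl(t)`) is available for contrast
experiments. Field geometry follows `dim = (image − rf)/stride + 1`.
The readout is a single-layer perceptron with logistic outputs trained by
the delta rule (`ΔW = α·I·E`, α = 0.1).

## Worked example

Train the bar preset (20×20 field, full-field receptive fields, 8 bar
directions) and read out its direction map:

```bash
python examples/02_direction_map.py
```

```
trained for 4 epochs (saturation criterion fired: True)
neurons preferring each direction (deg -> count):
    0 deg:  83
   45 deg:  95
   90 deg:  58
  135 deg:  43
  180 deg:  29
  225 deg:  50
  270 deg:  10
  315 deg:  32
all 8 directions represented: True
```

Every direction, including opposite pairs of the same orientation,
recruits its own neuron population — the signature of genuine direction
(not just orientation) selectivity. `examples/` holds one script per
capability: stimulus generation, direction maps, component-vs-pattern
motion, flow decoding, and noise robustness. The same protocols are
available from the shell:

```bash
nfmotion repro simulation1 --seed 3        # bar direction map bundle
nfmotion train --preset bar_v1 --rule symmetric --out sym_run
nfmotion robustness --noise salt_pepper --levels 10
```

Each run writes a bundle (resolved `config.yaml`, `network.npz`,
`map.csv`/`map.png`, `metrics.json`) that reproduces itself.

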