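"""Layered networks, the two-timescale training loop, and presets.

A :class:`LayeredNetwork` chains fields input -> NF1 (-> NF2): field k's
input sheet is the raw image for k = 0 and field k-1's settled activity
above. Training is layer-wise: a lower field is trained to saturation
(or its epoch cap) with everything else frozen before the next field is
trained. Within a sequence the network only ever sees the current frame;
motion history enters through the asymmetric lateral updates. Activity is
reset to zero between sequences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from . import stimuli as st
from .field import FieldParams, FieldState, afferent_response, init_state, reset_activity, settle
from .plasticity import LearningRule, apply_frame_update

__all__ = [
    "LayeredNetwork", "TrainingReport", "Preset", "load_preset",
    "present_sequence", "train_layer", "saturation_fraction",
]

PRESET_NAMES = ("bar_v1", "grating_plaid", "square", "rds_translate")


@dataclass
class LayeredNetwork:
    """Ordered fields with their wiring and learning rules."""

    image_size: int
    fields: list[FieldState]
    rules: list[LearningRule]
    name: str = "custom"

    def __post_init__(self):
        size = self.image_size
        for k, f in enumerate(self.fields):
            if f.params.input_size != size:
                raise ValueError(
                    f"field {k} expects input sheet {f.params.input_size}, "
                    f"but the layer below provides {size}")
            size = f.params.dim

    @property
    def n_fields(self) -> int:
        return len(self.fields)

    def reset(self) -> None:
        for f in self.fields:
            reset_activity(f)


def _settle_frame(network: LayeredNetwork, frame: np.ndarray, last: int,
                  steps: int | None = None) -> list[np.ndarray]:
    """Settle fields 0..last in lockstep on one frame.

    All fields iterate their lateral dynamics concurrently: at every
    settling step each field applies one lateral update and the field
    above reads its freshly updated activity. The image drive is constant
    within the frame; a higher field's afferent drive follows the lower
    field's settling trajectory. Each field starts from its previous
    frame's settled activity (zero after a reset), which is how stimulus
    order enters the response. Returns the settled grid per field and
    leaves them in ``field.eta_prev`` / ``field.eta``.
    """
    n_steps = max(network.fields[k].params.settling_steps for k in range(last + 1)) \
        if steps is None else steps
    S0 = afferent_response(network.fields[0], network.fields[0].params, frame)
    etas = [network.fields[k].eta_prev.copy() for k in range(last + 1)]
    for s in range(n_steps):
        inp = None
        for k in range(last + 1):
            f = network.fields[k]
            if s < f.params.settling_steps:
                S = S0 if k == 0 else afferent_response(f, f.params, inp)
                etas[k] = settle(f, f.params, S, eta0=etas[k], steps=1)
            inp = etas[k]
    for k in range(last + 1):
        network.fields[k].eta = etas[k]
        network.fields[k].eta_prev = etas[k].copy()
    return etas


def present_sequence(network: LayeredNetwork, sequence: st.StimulusSequence,
                     learn: bool = False, train_index: int | None = None,
                     up_to: int | None = None) -> list[np.ndarray]:
    """Present a sequence frame by frame; return each field's activity history.

    Resets all activity first. Per frame, all fields settle concurrently
    (see :func:`_settle_frame`); afterwards the field at ``train_index``
    adapts its weights if ``learn`` is set. Returns one
    ``(n_frames, dim, dim)`` stack per field (restricted to fields
    ``0..up_to`` if given).
    """
    network.reset()
    last = network.n_fields - 1 if up_to is None else up_to
    history: list[list[np.ndarray]] = [[] for _ in range(last + 1)]
    for frame in sequence.frames:
        prev = [network.fields[k].eta_prev.copy() for k in range(last + 1)]
        etas = _settle_frame(network, frame, last)
        if learn and train_index is not None and train_index <= last:
            f = network.fields[train_index]
            f.eta_prev = prev[train_index]  # restore: the update needs eta(t-1)
            inp = frame if train_index == 0 else etas[train_index - 1]
            apply_frame_update(f, f.params, network.rules[train_index], inp, etas[train_index])
        for k in range(last + 1):
            history[k].append(etas[k])
    return [np.stack(h) for h in history]


def saturation_fraction(delta_history: np.ndarray, epsilon: float) -> float:
    """Fraction of weight entries whose last-epoch |dW| is below ``epsilon``.

    Training stops once this reaches 0.8 ("80% of the weight changes
    approach zero").
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    d = np.abs(np.asarray(delta_history, dtype=float).ravel())
    if d.size == 0:
        return 1.0
    return float(np.mean(d < epsilon))


@dataclass
class TrainingReport:
    """Per-epoch bookkeeping of one layer's training run."""

    layer: int
    epochs_run: int = 0
    mean_abs_delta: dict = dc_field(default_factory=lambda: {"afferent": [], "excitatory": [], "inhibitory": []})
    saturation_trace: list = dc_field(default_factory=list)
    converged: bool = False
    seed: int | None = None


def _lower_trajectories(network: LayeredNetwork, sequence: st.StimulusSequence,
                        layer_index: int, n_steps: int) -> np.ndarray:
    """Per-step activity of field ``layer_index - 1`` over a whole sequence.

    Runs the frozen fields below the training layer in lockstep and
    records the input the training layer would see at every settling
    step: shape ``(n_frames, n_steps, dim, dim)``. With fixed weights and
    the per-sequence reset this trajectory is a deterministic function of
    the sequence, so it is computed once and reused across epochs.
    """
    below = layer_index - 1
    for k in range(below + 1):
        reset_activity(network.fields[k])
    out = np.empty((sequence.n_frames, n_steps,
                    network.fields[below].params.dim, network.fields[below].params.dim))
    for t, frame in enumerate(sequence.frames):
        S0 = afferent_response(network.fields[0], network.fields[0].params, frame)
        etas = [network.fields[k].eta_prev.copy() for k in range(below + 1)]
        for s in range(n_steps):
            inp = None
            for k in range(below + 1):
                f = network.fields[k]
                if s < f.params.settling_steps:
                    S = S0 if k == 0 else afferent_response(f, f.params, inp)
                    etas[k] = settle(f, f.params, S, eta0=etas[k], steps=1)
                inp = etas[k]
            out[t, s] = etas[below]
        for k in range(below + 1):
            network.fields[k].eta = etas[k]
            network.fields[k].eta_prev = etas[k].copy()
    return out


def train_layer(network: LayeredNetwork, layer_index: int,
                training_set: list[st.StimulusSequence], epochs: int | None = None,
                seed: int | None = None, saturation_epsilon_scale: float = 0.05,
                saturation_target: float = 0.8) -> TrainingReport:
    """Train one field on a sequence set with everything else frozen.

    Sequences are drawn in a random order each epoch (seeded). Runs up to
    ``epochs`` epochs (default: the field's preset cap) or until the
    saturation criterion fires: at least ``saturation_target`` (0.8) of
    the trainable weight entries changed by less than ``epsilon`` over
    the last epoch. ``epsilon`` is ``saturation_epsilon_scale`` times the
    first epoch's per-type mean |dW| — saturation means per-entry
    learning has slowed to a small fraction of its initial rate, which a
    persistent noise drive prevents.
    """
    f = network.fields[layer_index]
    rule = network.rules[layer_index]
    cap = f.params.epochs if epochs is None else epochs
    rng = np.random.default_rng(seed)
    report = TrainingReport(layer=layer_index, seed=seed)
    if cap == 0 or not training_set:
        return report

    n_steps = max(network.fields[k].params.settling_steps for k in range(layer_index + 1))
    if layer_index == 0:
        trajectories = None
    else:
        trajectories = [_lower_trajectories(network, seq, layer_index, n_steps)
                        for seq in training_set]
    aff_trainable = not (rule.freeze_afferent or f.afferent_frozen)
    ref_delta: dict[str, float] = {}

    for _ in range(cap):
        snap = {"excitatory": f.W_exc.copy(), "inhibitory": f.W_inhb.copy()}
        if aff_trainable:
            snap["afferent"] = f.W_aff.copy()
        order = rng.permutation(len(training_set))
        for si in order:
            reset_activity(f)
            seq = training_set[si]
            for t in range(seq.n_frames):
                eta = f.eta_prev.copy()
                if layer_index == 0:
                    inp = np.asarray(seq.frames[t], dtype=float)
                    S = afferent_response(f, f.params, inp)
                    eta = settle(f, f.params, S, eta0=eta)
                else:
                    for s in range(f.params.settling_steps):
                        S = afferent_response(f, f.params, trajectories[si][t, s])
                        eta = settle(f, f.params, S, eta0=eta, steps=1)
                    inp = trajectories[si][t, -1]
                apply_frame_update(f, f.params, rule, inp, eta)
        report.epochs_run += 1

        deltas, sat_parts = {}, []
        pairs = [("excitatory", f.W_exc, f.exc_valid), ("inhibitory", f.W_inhb, f.inhb_valid)]
        if aff_trainable:
            pairs.append(("afferent", f.W_aff, None))
        for name, W, mask in pairs:
            d = W - snap[name]
            on = np.abs(d[mask] if mask is not None else d.ravel())
            deltas[name] = float(np.mean(on))
            if name not in ref_delta:  # first epoch sets the reference learning rate
                ref_delta[name] = max(deltas[name], 1e-300)
            sat_parts.append(on < saturation_epsilon_scale * ref_delta[name])
        for name in report.mean_abs_delta:
            report.mean_abs_delta[name].append(deltas.get(name, 0.0))
        sat = float(np.mean(np.concatenate(sat_parts)))
        report.saturation_trace.append(sat)
        if sat >= saturation_target:
            report.converged = True
            break
    return report


# ---------------------------------------------------------------------------
# Presets

@dataclass
class Preset:
    """A named parameter set plus its stimulus builders."""

    name: str
    config: dict

    def build_network(self, seed: int | None = None,
                      rule_mode: str = "asymmetric") -> LayeredNetwork:
        rng = np.random.default_rng(seed)
        fields, rules = [], []
        input_size = self.config["image_size"]
        for fc in self.config["fields"]:
            params = FieldParams(
                dim=fc["dim"], rf=fc["rf"], input_size=input_size,
                stride=fc.get("stride"), r_exc=fc["r_exc"], r_inhb=fc["r_inhb"],
                gamma_aff=fc["gamma_aff"], gamma_exc=fc["gamma_exc"],
                gamma_inhb=fc["gamma_inhb"], alpha_aff=fc["alpha_aff"],
                alpha_exc=fc["alpha_exc"], alpha_inhb=fc["alpha_inhb"],
                settling_steps=fc["settling_steps"], epochs=fc["epochs"],
                settle_lo=fc.get("settle_lo"), settle_hi=fc.get("settle_hi"),
                settle_damping=fc.get("settle_damping", 1.0))
            unit_aff = bool(fc.get("unit_afferent", False))
            fields.append(init_state(params, rng, unit_afferent=unit_aff))
            rules.append(LearningRule(mode=rule_mode, freeze_afferent=unit_aff))
            input_size = fc["dim"]
        return LayeredNetwork(self.config["image_size"], fields, rules, name=self.name)

    def training_sets(self, seed: int | None = None) -> dict:
        """The stimulus sets this preset is trained/probed with, keyed by role."""
        sc = self.config["stimuli"]
        kind = sc["kind"]
        if kind == "bar":
            bars = st.build_bar_set(bar_len=sc["bar_len"], bar_width=sc["bar_width"],
                                    n_frames=sc["n_frames"], step_px=sc["step_px"])
            return {"train": [bars], "probe": bars}
        if kind == "grating_plaid":
            gratings = st.build_grating_set(spatial_period_px=sc["spatial_period_px"],
                                            n_frames=sc["n_frames"])
            plaids = st.build_plaid_set(spatial_period_px=sc["spatial_period_px"],
                                        n_frames=sc["n_frames"])
            return {"train": [gratings, plaids], "probe": plaids}
        if kind == "square":
            squares = st.build_square_set(square_size=sc["square_size"], n_frames=sc["n_frames"])
            return {"train": [squares, squares], "probe": squares}
        if kind == "rds_translate":
            train, test = st.build_rds_sets(seed if seed is not None else 0,
                                            n_configurations=sc["n_configurations"],
                                            n_train_configurations=sc["n_train_configurations"],
                                            n_frames=sc["n_frames"])
            return {"train": [train, train], "probe": train, "test": test}
        raise ValueError(f"unknown stimulus kind {kind!r}")


def load_preset(name: str) -> Preset:
    """Load one of the shipped parameter presets.

    Available: ``bar_v1`` (single-field direction map),
    ``grating_plaid`` and ``square`` (two-field component/pattern motion),
    ``rds_translate`` (two-field translational flow + decoder).
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    path = importlib.resources.files("nfmotion.presets").joinpath(f"{name}.yaml")
    config = yaml.safe_load(path.read_text())
    return Preset(name=name, config=config)
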