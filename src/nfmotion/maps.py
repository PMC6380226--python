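"""Topographic preference maps and robustness analysis.

After training, every neuron is assigned the stimulus direction that
evokes its maximum settled response over a probe set — the
direction-selectivity (or pattern-/flow-selectivity) map. Robustness of
a trained map to perturbed stimuli is summarized by the robustness index

    RI = 1 - (# neurons whose preferred direction changed) / (# neurons),

computed against the clean-reference map per noise level or bar length.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import stimuli as st
from .network import LayeredNetwork, Preset, present_sequence, train_layer

__all__ = [
    "DirectionMap", "RobustnessCurve", "preferred_directions",
    "robustness_index", "run_noise_sweep", "run_noise_training_trials",
    "run_bar_length_sweep", "map_to_dataframe",
    "SALT_PEPPER_LEVELS", "GAUSSIAN_LEVELS",
]

#: Default robustness sweeps: salt-and-pepper density 0.01 to 0.99 and
#: Gaussian variance 0.02 to 1.0, both in steps of 0.02 (50 levels each).
SALT_PEPPER_LEVELS = tuple(np.round(np.arange(0.01, 0.999, 0.02), 4))
GAUSSIAN_LEVELS = tuple(np.round(np.arange(0.02, 1.0001, 0.02), 4))


@dataclass
class DirectionMap:
    """Per-neuron preferred direction (deg) and peak settled response."""

    preferred_deg: np.ndarray  # (dim, dim)
    peak_response: np.ndarray  # (dim, dim)
    directions: tuple
    stimulus_set_id: str = ""

    @property
    def dim(self) -> int:
        return self.preferred_deg.shape[0]

    def represented_directions(self) -> set:
        return set(np.unique(self.preferred_deg).tolist())


@dataclass
class RobustnessCurve:
    """RI (and deviated-neuron counts) along a perturbation sweep."""

    noise_levels: np.ndarray
    ri: np.ndarray
    deviated_counts: np.ndarray
    trial_seed: int | None = None
    kind: str = ""


def _sequence_responses(network: LayeredNetwork, sequence: st.StimulusSequence,
                        layer: int) -> np.ndarray:
    """Per-neuron maximum settled activity over the sequence's frames."""
    hist = present_sequence(network, sequence, learn=False, up_to=layer)
    return hist[layer].max(axis=0)


def preferred_directions(network: LayeredNetwork, probe_sequences: list[st.StimulusSequence],
                         layer: int | None = None, stimulus_set_id: str = "") -> DirectionMap:
    """Assign every neuron the probe direction evoking its maximum response.

    Probing is read-only (weights untouched). Ties are broken toward the
    lowest direction angle; probes sharing a direction are pooled by
    taking their maximum response.
    """
    if not probe_sequences:
        raise ValueError("probe set is empty")
    layer = network.n_fields - 1 if layer is None else layer
    directions = sorted({s.direction_deg for s in probe_sequences})
    by_dir = {d: [] for d in directions}
    for s in probe_sequences:
        by_dir[s.direction_deg].append(_sequence_responses(network, s, layer))
    resp = np.stack([np.max(by_dir[d], axis=0) for d in directions])  # (n_dir, dim, dim)
    best = resp.argmax(axis=0)  # argmax picks the first (lowest-angle) maximum
    pref = np.asarray(directions, dtype=float)[best]
    peak = resp.max(axis=0)
    return DirectionMap(pref, peak, tuple(directions), stimulus_set_id)


def robustness_index(reference_map: DirectionMap, perturbed_map: DirectionMap) -> float:
    """``1 - fraction of neurons whose preferred direction changed``."""
    if reference_map.preferred_deg.shape != perturbed_map.preferred_deg.shape:
        raise ValueError("maps cover different sheets")
    deviated = np.count_nonzero(reference_map.preferred_deg != perturbed_map.preferred_deg)
    return 1.0 - deviated / reference_map.preferred_deg.size


def _noisy(seq: st.StimulusSequence, kind: str, level: float, seed: int) -> st.StimulusSequence:
    if level == 0:
        return seq
    if kind == "salt_pepper":
        return st.add_salt_pepper_noise(seq, level, seed)
    if kind == "gaussian":
        return st.add_gaussian_noise(seq, 0.0, level, seed)
    raise ValueError(f"unknown noise kind {kind!r}")


def run_noise_sweep(trained_network: LayeredNetwork, probe_sequences: list[st.StimulusSequence],
                    noise_kind: str, levels=None, seed: int = 0,
                    layer: int | None = None) -> RobustnessCurve:
    """Probe a trained (frozen) network with increasingly noisy stimuli.

    Per level the probe set is rebuilt with noise, the map recomputed and
    compared (RI) against the clean-reference map. Defaults reproduce the
    50-level sweeps (salt-and-pepper density or Gaussian variance).
    """
    if levels is None:
        levels = SALT_PEPPER_LEVELS if noise_kind == "salt_pepper" else GAUSSIAN_LEVELS
    levels = np.asarray(levels, dtype=float)
    ref = preferred_directions(trained_network, probe_sequences, layer=layer)
    n = ref.preferred_deg.size
    ri, deviated = [], []
    for i, lv in enumerate(levels):
        noisy = [_noisy(s, noise_kind, lv, seed + 7919 * j) for j, s in enumerate(probe_sequences)]
        m = preferred_directions(trained_network, noisy, layer=layer)
        r = robustness_index(ref, m)
        ri.append(r)
        deviated.append(round((1.0 - r) * n))
    return RobustnessCurve(levels, np.asarray(ri), np.asarray(deviated), seed, noise_kind)


def run_noise_training_trials(preset: Preset, noise_kind: str, n_trials: int,
                              levels, seed: int = 0, epochs: int | None = None) -> pd.DataFrame:
    """Retrain from scratch on noisy stimuli and judge convergence per trial.

    For each trial and noise level a fresh single-field network (the
    preset's first field) is trained on a noisy copy of the training set.
    "Converged" = the saturation criterion fired within the epoch cap AND
    every training direction is represented in the resulting map. Returns
    a tidy table (trial, noise level, converged, saturation, epochs_run)
    for band-wise summaries.
    """
    levels = np.asarray(levels, dtype=float)
    rows = []
    rng = np.random.default_rng(seed)
    for trial in range(n_trials):
        for lv in levels:
            trial_seed = int(rng.integers(0, 2**31 - 1))
            net = preset.build_network(seed=trial_seed)
            sets = preset.training_sets(seed=trial_seed)
            clean = sets["train"][0]
            noisy = [_noisy(s, noise_kind, float(lv), trial_seed + 31 * j)
                     for j, s in enumerate(clean)]
            report = train_layer(net, 0, noisy, epochs=epochs, seed=trial_seed)
            m = preferred_directions(net, noisy, layer=0)
            covered = m.represented_directions() >= {s.direction_deg for s in clean}
            rows.append({"trial": trial, "noise_level": float(lv),
                         "converged": bool(report.converged and covered),
                         "saturation": report.saturation_trace[-1] if report.saturation_trace else 0.0,
                         "epochs_run": report.epochs_run})
    return pd.DataFrame(rows)


def run_bar_length_sweep(trained_network: LayeredNetwork, lengths=range(15, 36),
                         reference_len: int = 30, layer: int | None = None,
                         **bar_kw) -> RobustnessCurve:
    """RI of a bar-trained network probed with bars of varying length.

    The reference map comes from ``reference_len`` (the training length);
    each probe length contributes one RI value.
    """
    ref_probe = st.build_bar_set(bar_len=reference_len, **bar_kw)
    ref = preferred_directions(trained_network, ref_probe, layer=layer)
    n = ref.preferred_deg.size
    lengths = np.asarray(list(lengths))
    ri, deviated = [], []
    for L in lengths:
        m = preferred_directions(trained_network, st.build_bar_set(bar_len=int(L), **bar_kw),
                                 layer=layer)
        r = robustness_index(ref, m)
        ri.append(r)
        deviated.append(round((1.0 - r) * n))
    return RobustnessCurve(lengths.astype(float), np.asarray(ri), np.asarray(deviated), None,
                           "bar_length")


def map_to_dataframe(direction_map: DirectionMap) -> pd.DataFrame:
    """Flatten a map to (row, col, preferred_deg, peak) for CSV export."""
    dim = direction_map.dim
    rr, cc = np.meshgrid(np.arange(dim), np.arange(dim), indexing="ij")
    return pd.DataFrame({
        "row": rr.ravel(), "col": cc.ravel(),
        "preferred_deg": direction_map.preferred_deg.ravel(),
        "peak": direction_map.peak_response.ravel(),
    })
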