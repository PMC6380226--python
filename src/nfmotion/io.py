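"""Persistence and figure export.

Array state (weights, activities) goes into ``.npz`` archives; maps and
robustness curves into CSV; figures into PNG. Every experiment bundle
also carries its resolved configuration as YAML so a run can be
reproduced from its output directory alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .decoder import PerceptronModel
from .maps import DirectionMap, RobustnessCurve, map_to_dataframe
from .network import LayeredNetwork
from .stimuli import StimulusSequence

__all__ = [
    "save_network", "load_network_arrays", "save_perceptron", "load_perceptron",
    "save_map", "save_curve", "save_sequences", "save_frames_png", "plot_direction_map",
    "plot_robustness_curve", "plot_error_trace", "write_yaml", "write_json",
]


def save_network(path, network: LayeredNetwork) -> None:
    """All field weights and activities in one ``.npz`` archive."""
    entries = {"image_size": np.array(network.image_size), "n_fields": np.array(network.n_fields)}
    for k, f in enumerate(network.fields):
        entries[f"field{k}_W_aff"] = f.W_aff
        entries[f"field{k}_W_exc"] = f.W_exc_dense()
        entries[f"field{k}_W_inhb"] = f.W_inhb_dense()
        entries[f"field{k}_eta"] = f.eta
        entries[f"field{k}_dim"] = np.array(f.params.dim)
        entries[f"field{k}_rf"] = np.array(f.params.rf)
    np.savez_compressed(path, **entries)


def load_network_arrays(path) -> dict:
    """Raw archive contents of :func:`save_network` (arrays keyed by name)."""
    with np.load(path) as z:
        return {k: z[k].copy() for k in z.files}


def save_perceptron(path, model: PerceptronModel) -> None:
    np.savez_compressed(path, W=model.W, b=model.b,
                        classes=np.asarray(model.classes, dtype=float),
                        alpha=np.array(model.alpha),
                        error_trace=np.asarray(model.error_trace, dtype=float))


def load_perceptron(path) -> PerceptronModel:
    with np.load(path) as z:
        m = PerceptronModel(z["W"].copy(), z["b"].copy(),
                            tuple(z["classes"].tolist()), float(z["alpha"]))
        m.error_trace = z["error_trace"].tolist()
    return m


def save_map(path, direction_map: DirectionMap) -> None:
    """CSV with one row per neuron: row, col, preferred_deg, peak."""
    map_to_dataframe(direction_map).to_csv(path, index=False)


def save_curve(path, curve: RobustnessCurve) -> None:
    pd.DataFrame({"noise_level": curve.noise_levels, "ri": curve.ri,
                  "deviated": curve.deviated_counts}).to_csv(path, index=False)


def save_sequences(path, sequences: list[StimulusSequence], manifest_path=None) -> None:
    """Stacked-array archive of sequences plus an optional CSV manifest."""
    entries = {f"seq{i}": s.frames for i, s in enumerate(sequences)}
    np.savez_compressed(path, **entries)
    if manifest_path is not None:
        pd.DataFrame([{"index": i, "kind": s.kind, "direction_deg": s.direction_deg,
                       "n_frames": s.n_frames, **{k: v for k, v in s.meta.items()
                                                  if np.isscalar(v) or v is None}}
                      for i, s in enumerate(sequences)]).to_csv(manifest_path, index=False)


def save_frames_png(directory, sequence: StimulusSequence, prefix: str = "frame") -> None:
    """One grayscale PNG per frame, for visual inspection of a sequence."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(sequence.frames):
        plt.imsave(directory / f"{prefix}_{t:03d}.png", frame, cmap="gray",
                   vmin=0.0, vmax=1.0)


def plot_direction_map(path, direction_map: DirectionMap, title: str = "") -> None:
    """Quiver rendering: arrow = preferred direction, length = peak response."""
    dim = direction_map.dim
    rr, cc = np.meshgrid(np.arange(dim), np.arange(dim), indexing="ij")
    th = np.deg2rad(direction_map.preferred_deg)
    mag = direction_map.peak_response
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(direction_map.preferred_deg, cmap="hsv", vmin=0, vmax=360, alpha=0.35,
              origin="upper")
    ax.quiver(cc, rr, mag * np.cos(th), mag * np.sin(th), angles="xy",
              scale_units="xy", scale=1.2, width=0.004)
    ax.set_title(title or "preferred-direction map")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_robustness_curve(path, curve: RobustnessCurve, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.noise_levels, curve.ri, marker="o", ms=3)
    ax.set_xlabel(curve.kind or "noise level")
    ax.set_ylabel("robustness index")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(title or "robustness to input perturbation")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_error_trace(path, error_trace, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.asarray(error_trace))
    ax.set_xlabel("epoch")
    ax.set_ylabel("sum-squared error")
    ax.set_title(title or "perceptron training error")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
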