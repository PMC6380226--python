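"""Single-layer multiclass perceptron readout.

A linear probe over the settled activity of a trained field: logistic
outputs, delta-rule online updates (``dW = alpha * I * E``,
``db = alpha * E`` with error ``E = y - O``), argmax classification.
The readout is not part of the modelled motion pathway — it only
quantifies how decodable the field's population code is.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import stimuli as st
from .network import LayeredNetwork, present_sequence

__all__ = [
    "PerceptronModel", "perceptron_forward", "train_perceptron",
    "decode_accuracy", "sequence_features",
]


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class PerceptronModel:
    """Readout weights, per-class biases and class labels."""

    W: np.ndarray            # (n_classes, n_inputs)
    b: np.ndarray            # (n_classes,)
    classes: tuple
    alpha: float = 0.1
    error_trace: list = dc_field(default_factory=list)

    @classmethod
    def zeros(cls, n_inputs: int, classes, alpha: float = 0.1) -> "PerceptronModel":
        classes = tuple(classes)
        return cls(np.zeros((len(classes), n_inputs)), np.zeros(len(classes)), classes, alpha)


def perceptron_forward(model: PerceptronModel, input_vector: np.ndarray) -> np.ndarray:
    """Per-class logistic outputs ``O_i = g(sum_j W_ij I_j + b_i)``."""
    x = np.asarray(input_vector, dtype=float).ravel()
    if x.size != model.W.shape[1]:
        raise ValueError(f"input dimension {x.size} != model dimension {model.W.shape[1]}")
    return _logistic(model.W @ x + model.b)


def train_perceptron(model: PerceptronModel, features: np.ndarray, labels,
                     epochs: int = 300, seed: int | None = None) -> PerceptronModel:
    """Online delta-rule training on one-hot targets, shuffled per epoch.

    Per sample: ``E = y - O``, ``W += alpha * outer(E, I)``,
    ``b += alpha * E``. Records the per-epoch sum-squared error in
    ``model.error_trace``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a nonempty (n_samples, n_inputs) array")
    class_index = {c: i for i, c in enumerate(model.classes)}
    y_idx = np.array([class_index[l] for l in labels])
    rng = np.random.default_rng(seed)
    for _ in range(epochs):
        sse = 0.0
        for i in rng.permutation(X.shape[0]):
            target = np.zeros(len(model.classes))
            target[y_idx[i]] = 1.0
            out = perceptron_forward(model, X[i])
            err = target - out
            model.W += model.alpha * np.outer(err, X[i])
            model.b += model.alpha * err
            sse += float(err @ err)
        model.error_trace.append(sse)
    return model


def decode_accuracy(model: PerceptronModel, features: np.ndarray, labels) -> float:
    """Fraction of samples whose argmax output matches the label."""
    X = np.asarray(features, dtype=float)
    preds = [model.classes[int(np.argmax(perceptron_forward(model, x)))] for x in X]
    return float(np.mean([p == l for p, l in zip(preds, labels)]))


def sequence_features(network: LayeredNetwork, sequences: list[st.StimulusSequence],
                      layer: int | None = None, reduce: str = "final") -> tuple[np.ndarray, list]:
    """Flattened settled-activity feature vector and label per sequence.

    ``reduce='final'`` (default) takes the last frame's settled activity
    of the source field — the flow response is nearly stabilized by then;
    ``reduce='mean'`` averages over frames.
    """
    layer = network.n_fields - 1 if layer is None else layer
    feats, labels = [], []
    for s in sequences:
        hist = present_sequence(network, s, learn=False, up_to=layer)[layer]
        v = hist[-1] if reduce == "final" else hist.mean(axis=0)
        feats.append(v.ravel())
        labels.append(s.direction_deg)
    return np.stack(feats), labels
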