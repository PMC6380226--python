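"""Weight adaptation: Hebbian updates and divisive normalization.

The afferent rule is plain Hebb (input x settled activity). Lateral
weights use a temporally *asymmetric* Hebbian rule — presynaptic activity
from the previous frame times the rectified increase of postsynaptic
activity on the current frame — which is what imprints motion order into
the lateral circuit; a temporally symmetric control rule is provided for
the contrast experiment. After every frame each neuron's incoming
weights of each type (afferent, excitatory, inhibitory) are divisively
normalized to unit sum, providing the competition that drives
self-organization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .field import FieldParams, FieldState, extract_patches

logger = logging.getLogger(__name__)

__all__ = [
    "LearningRule", "afferent_delta", "lateral_delta_asymmetric",
    "lateral_delta_symmetric", "divisive_normalize", "apply_frame_update",
]


@dataclass
class LearningRule:
    """Which lateral rule to apply and whether afferents adapt.

    ``mode`` is ``asymmetric`` (default; motion-order sensitive) or
    ``symmetric`` (temporally symmetric control). ``freeze_afferent``
    leaves the afferent weights untouched (fixed-unit-afferent mode used
    with random-dot stimuli). Learning rates live on
    :class:`~nfmotion.field.FieldParams`.
    """

    mode: str = "asymmetric"
    freeze_afferent: bool = False

    def __post_init__(self):
        if self.mode not in ("asymmetric", "symmetric"):
            raise ValueError(f"unknown learning mode {self.mode!r}")


def afferent_delta(input_patch, eta_ij, alpha_aff):
    """Hebbian afferent increment ``alpha * X * eta`` (elementwise)."""
    return alpha_aff * np.asarray(input_patch, dtype=float) * eta_ij


def lateral_delta_asymmetric(eta_post_t, eta_post_tm1, eta_pre_tm1, alpha):
    """``alpha * max(0, eta_post(t) - eta_post(t-1)) * eta_pre(t-1)``.

    Zero whenever postsynaptic activity is non-increasing, and zero on the
    first frame after a reset (presynaptic factor is 0) — only neurons
    whose activity *rises* strengthen their incoming lateral weights from
    previously active neurons.
    """
    return alpha * np.maximum(0.0, eta_post_t - eta_post_tm1) * eta_pre_tm1


def lateral_delta_symmetric(eta_post_t, eta_pre_t, alpha):
    """Temporally symmetric control: ``alpha * eta_post(t) * eta_pre(t)``."""
    return alpha * np.asarray(eta_post_t, dtype=float) * eta_pre_t


def divisive_normalize(weights_in, deltas_in):
    """Divisively normalize one neuron's incoming weights of one type.

    ``W_new = (W + dW) / sum(W + dW)``; the result sums to exactly 1.
    A zero denominator (dead neuron) leaves the weights unchanged with a
    warning.
    """
    w = np.asarray(weights_in, dtype=float) + np.asarray(deltas_in, dtype=float)
    s = w.sum()
    if s <= 0:
        logger.warning("divisive_normalize: zero incoming weight sum; leaving weights unchanged")
        return np.asarray(weights_in, dtype=float).copy()
    return w / s


def _update_rows(W: np.ndarray, dW: np.ndarray) -> None:
    """In-place ``W <- normalize_rows(W + dW)``, skipping zero-sum rows."""
    W += dW
    s = W.sum(axis=1, keepdims=True)
    bad = s <= 0
    if bad.any():
        logger.warning("divisive normalization skipped for %d dead neurons", int(bad.sum()))
        s = np.where(bad, 1.0, s)
    W /= s


def apply_frame_update(state: FieldState, params: FieldParams, rule: LearningRule,
                       input_grid: np.ndarray, eta_t: np.ndarray) -> FieldState:
    """One per-frame weight update after settling.

    Updates afferent (unless frozen), excitatory and inhibitory weights by
    their rules, normalizes each type separately per postsynaptic neuron,
    and advances ``eta_prev`` to the current settled activity. The new
    weights take effect from the next frame's settling onward.
    """
    eta = np.asarray(eta_t, dtype=float).ravel()
    eta_prev = state.eta_prev.ravel()

    if not (rule.freeze_afferent or state.afferent_frozen):
        X = extract_patches(state, input_grid)
        _update_rows(state.W_aff, params.alpha_aff * eta[:, None] * X)

    if rule.mode == "asymmetric":
        post = np.maximum(0.0, eta - eta_prev)
        pre = eta_prev
    else:
        post = eta
        pre = eta
    dE = post[:, None] * pre[state.exc_idx] * state.exc_valid
    dI = post[:, None] * pre[state.inhb_idx] * state.inhb_valid
    _update_rows(state.W_exc, params.alpha_exc * dE)
    _update_rows(state.W_inhb, params.alpha_inhb * dI)

    state.eta = np.asarray(eta_t, dtype=float).reshape(params.dim, params.dim).copy()
    state.eta_prev = state.eta.copy()
    return state
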