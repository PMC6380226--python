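"""Neural-field dynamics: afferent drive and lateral settling.

A field is a ``dim x dim`` sheet of rate neurons. Each neuron sees an
``rf x rf`` patch of the input sheet through nonnegative afferent weights;
its feedforward drive is the scaled inner product of weights and patch,
squashed by a piecewise-linear sigmoid. Lateral interactions — excitatory
within radius ``r_exc``, inhibitory in the annulus ``(r_exc, r_inhb]`` —
are then iterated for ``settling_steps`` steps at fixed afferent drive,
focusing the initially widespread response into a localized activity
bubble. Lateral weights are directed (stored independently per ordered
neuron pair): their asymmetry is what lets the field encode motion.

Settling starts from the previous frame's settled activity (zero at the
start of a sequence), so a field's response to a frame depends on the
recent stimulus history — remove that continuity and the settled response
becomes a pure per-frame function of the image, which carries no motion
information at probe time.

Lateral weights are stored as per-neuron neighbor lists (``(N, K)``
weight and index arrays) rather than dense ``(N, N)`` matrices; dense
views are available for inspection and serialization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FieldParams", "FieldState", "sigma", "derive_dim",
    "afferent_response", "settle", "reset_activity", "init_state",
]


def sigma(x, lo: float = 0.0, hi: float = 1.0):
    """Piecewise-linear sigmoid: 0 below ``lo``, 1 above ``hi``, linear between.

    With the default thresholds this is the identity on [0, 1] and a hard
    clip outside, keeping all activities bounded.
    """
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def derive_dim(image_size: int, rf: int, stride: int) -> int:
    """Field side length for an input sheet tiled by rf-sized patches.

    ``dim = (image_size - rf) / stride + 1``; the geometry must tile
    exactly. On a non-divisible geometry the error lists the strides that
    would tile.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    span = image_size - rf
    if span < 0:
        raise ValueError(f"rf={rf} larger than image_size={image_size}")
    if span % stride:
        valid = [s for s in range(1, span + 1) if span % s == 0]
        raise ValueError(
            f"(image_size - rf) = {span} is not divisible by stride {stride}; "
            f"valid strides: {valid}")
    return span // stride + 1


@dataclass
class FieldParams:
    """All per-field scalars of a simulation preset.

    Attributes
    ----------
    dim : int
        Sheet side length (neurons).
    rf : int
        Receptive-field side length, in input-sheet units.
    input_size : int
        Side length of the input sheet (image pixels or lower-field neurons).
    stride : int or None
        RF displacement between neighbouring neurons. ``None`` places the
        RF origins at evenly spaced (rounded) offsets — required where a
        preset's ``dim`` has no exact integer-stride tiling, and
        degenerating to a shared full-field RF when ``rf == input_size``.
    r_exc, r_inhb : float
        Excitatory disc radius and inhibitory outer radius (in neurons);
        inhibition acts on the annulus ``r_exc < d <= r_inhb``.
    gamma_aff, gamma_exc, gamma_inhb : float
        Gains of the afferent, excitatory and inhibitory terms.
    alpha_aff, alpha_exc, alpha_inhb : float
        Hebbian learning rates per connection type.
    settling_steps : int
        Lateral-interaction iterations per frame (Ts).
    epochs : int
        Training-epoch cap for this field.
    metric : str
        Neighbourhood metric, ``euclidean`` (circular disc/annulus,
        default) or ``chebyshev`` (square).
    sigma_lo, sigma_hi : float
        Thresholds of the piecewise-linear sigmoid applied to the
        afferent drive (defaults 0/1: identity on [0, 1]).
    settle_lo, settle_hi : float or None
        Thresholds of the sigmoid used inside the settling iteration,
        where the total drive (afferent plus lateral) exceeds the [0, 1]
        range. ``None`` falls back to ``sigma_lo`` / ``sigma_hi``. A
        positive ``settle_lo`` lets surround inhibition silence weakly
        driven neurons and confine the activity bubble.
    settle_damping : float
        Relaxation factor of the synchronous settling update
        (``eta <- (1 - d) * eta + d * sigma(...)``). 1 is the plain
        synchronous iteration; values below 1 damp the period-2
        oscillations that strong surround inhibition can otherwise
        excite, without moving the fixed points.
    """

    dim: int
    rf: int
    input_size: int
    stride: int | None = None
    r_exc: float = 3.0
    r_inhb: float = 10.0
    gamma_aff: float = 1.0
    gamma_exc: float = 1.0
    gamma_inhb: float = 1.0
    alpha_aff: float = 0.05
    alpha_exc: float = 0.05
    alpha_inhb: float = 0.05
    settling_steps: int = 10
    epochs: int = 500
    metric: str = "euclidean"
    sigma_lo: float = 0.0
    sigma_hi: float = 1.0
    settle_lo: float | None = None
    settle_hi: float | None = None
    settle_damping: float = 1.0

    def __post_init__(self):
        if self.r_exc >= self.r_inhb:
            raise ValueError(f"r_exc ({self.r_exc}) must be < r_inhb ({self.r_inhb})")
        if min(self.gamma_aff, self.gamma_exc, self.gamma_inhb) < 0:
            raise ValueError("gains must be >= 0")
        if self.settling_steps < 1:
            raise ValueError("settling_steps must be >= 1")
        if self.metric not in ("euclidean", "chebyshev"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.rf > self.input_size:
            raise ValueError(f"rf={self.rf} exceeds input_size={self.input_size}")
        if self.stride is not None:
            if derive_dim(self.input_size, self.rf, self.stride) != self.dim:
                raise ValueError(
                    f"stride {self.stride} yields dim "
                    f"{derive_dim(self.input_size, self.rf, self.stride)}, preset says {self.dim}")

    @property
    def n_neurons(self) -> int:
        return self.dim * self.dim

    @property
    def settle_thresholds(self) -> tuple[float, float]:
        lo = self.sigma_lo if self.settle_lo is None else self.settle_lo
        hi = self.sigma_hi if self.settle_hi is None else self.settle_hi
        return lo, hi

    def rf_offsets(self) -> np.ndarray:
        """Per-axis RF origin offsets into the input sheet (length ``dim``)."""
        if self.stride is not None:
            return np.arange(self.dim) * self.stride
        return np.round(np.linspace(0, self.input_size - self.rf, self.dim)).astype(int)


def _neighbor_lists(params: FieldParams, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor index array (N, K) + validity mask for one lateral type.

    ``kind='exc'``: distances 0 < d <= r_exc; ``kind='inhb'``: the annulus
    r_exc < d <= r_inhb. Neighborhoods are truncated at the sheet edges
    (the retinotopic sheet is not a torus); invalid (padding) slots point
    at the neuron itself and are masked out everywhere.
    """
    dim = params.dim
    span = int(np.floor(params.r_inhb if kind == "inhb" else params.r_exc))
    offs = np.arange(-span, span + 1)
    orr, occ = np.meshgrid(offs, offs, indexing="ij")
    if params.metric == "euclidean":
        d = np.hypot(orr, occ)
    else:
        d = np.maximum(np.abs(orr), np.abs(occ))
    if kind == "exc":
        sel = (d > 0) & (d <= params.r_exc)
    else:
        sel = (d > params.r_exc) & (d <= params.r_inhb)
    dr, dc = orr[sel], occ[sel]

    rr, cc = np.meshgrid(np.arange(dim), np.arange(dim), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    nr = rr[:, None] + dr[None, :]
    nc = cc[:, None] + dc[None, :]
    valid = (nr >= 0) & (nr < dim) & (nc >= 0) & (nc < dim)
    self_idx = (rr * dim + cc)[:, None]
    idx = np.where(valid, nr * dim + nc, self_idx)
    return idx.astype(np.intp), valid


@dataclass
class FieldState:
    """Mutable state of one field: weights and activity.

    ``W_aff`` is (N, rf*rf). Lateral weights are neighbor lists: row ``i``
    of ``W_exc`` (``W_inhb``) holds the incoming weights of postsynaptic
    neuron ``i`` from the presynaptic neurons listed in ``exc_idx[i]``
    (``inhb_idx[i]``) — the excitatory disc and inhibitory annulus
    respectively, truncated at the sheet edge. ``eta`` / ``eta_prev`` are
    the settled activity grids of the current and previous frame.
    """

    params: FieldParams
    W_aff: np.ndarray
    W_exc: np.ndarray
    W_inhb: np.ndarray
    eta: np.ndarray
    eta_prev: np.ndarray
    exc_idx: np.ndarray
    exc_valid: np.ndarray
    inhb_idx: np.ndarray
    inhb_valid: np.ndarray
    patch_idx: np.ndarray
    afferent_frozen: bool = False

    def copy(self) -> "FieldState":
        return dataclasses.replace(
            self, W_aff=self.W_aff.copy(), W_exc=self.W_exc.copy(),
            W_inhb=self.W_inhb.copy(), eta=self.eta.copy(), eta_prev=self.eta_prev.copy())

    def _dense(self, W: np.ndarray, idx: np.ndarray, valid: np.ndarray) -> np.ndarray:
        n = self.params.n_neurons
        D = np.zeros((n, n))
        rows = np.repeat(np.arange(n), idx.shape[1]).reshape(idx.shape)
        D[rows[valid], idx[valid]] = W[valid]
        return D

    def W_exc_dense(self) -> np.ndarray:
        """Dense (N, N) excitatory matrix, row = postsynaptic neuron."""
        return self._dense(self.W_exc, self.exc_idx, self.exc_valid)

    def W_inhb_dense(self) -> np.ndarray:
        """Dense (N, N) inhibitory matrix, row = postsynaptic neuron."""
        return self._dense(self.W_inhb, self.inhb_idx, self.inhb_valid)

    def set_lateral_dense(self, W_exc: np.ndarray | None = None,
                          W_inhb: np.ndarray | None = None) -> None:
        """Load dense lateral matrices (entries off the support are ignored)."""
        if W_exc is not None:
            rows = np.repeat(np.arange(self.params.n_neurons),
                             self.exc_idx.shape[1]).reshape(self.exc_idx.shape)
            self.W_exc = np.where(self.exc_valid, np.asarray(W_exc, float)[rows, self.exc_idx], 0.0)
        if W_inhb is not None:
            rows = np.repeat(np.arange(self.params.n_neurons),
                             self.inhb_idx.shape[1]).reshape(self.inhb_idx.shape)
            self.W_inhb = np.where(self.inhb_valid, np.asarray(W_inhb, float)[rows, self.inhb_idx], 0.0)


def _patch_indices(params: FieldParams) -> np.ndarray:
    """(N, rf*rf) indices into the flattened input sheet, one row per neuron."""
    off = params.rf_offsets()
    base = np.arange(params.rf)
    patch = (base[:, None] * params.input_size + base[None, :]).ravel()
    origins = (off[:, None] * params.input_size + off[None, :]).ravel()  # row-major neurons
    return origins[:, None] + patch[None, :]


def _normalize_rows(W: np.ndarray) -> np.ndarray:
    s = W.sum(axis=1, keepdims=True)
    np.divide(W, s, out=W, where=s > 0)
    return W


def init_state(params: FieldParams, rng: np.random.Generator,
               unit_afferent: bool = False) -> FieldState:
    """Random nonnegative weights, normalized to unit incoming sum per type.

    With ``unit_afferent`` the afferent weights are fixed at 1 (not
    normalized, excluded from learning) — the configuration used to make
    a field's drive position-independent for random-dot stimuli.
    """
    n = params.n_neurons
    exc_idx, exc_valid = _neighbor_lists(params, "exc")
    inhb_idx, inhb_valid = _neighbor_lists(params, "inhb")
    if unit_afferent:
        W_aff = np.ones((n, params.rf * params.rf))
    else:
        W_aff = _normalize_rows(rng.uniform(0.0, 1.0, size=(n, params.rf * params.rf)))
    W_exc = _normalize_rows(rng.uniform(0.0, 1.0, size=exc_idx.shape) * exc_valid)
    W_inhb = _normalize_rows(rng.uniform(0.0, 1.0, size=inhb_idx.shape) * inhb_valid)
    zero = np.zeros((params.dim, params.dim))
    return FieldState(params, W_aff, W_exc, W_inhb, zero, zero.copy(),
                      exc_idx, exc_valid, inhb_idx, inhb_valid,
                      _patch_indices(params), afferent_frozen=unit_afferent)


def extract_patches(state: FieldState, input_grid: np.ndarray) -> np.ndarray:
    """(N, rf*rf) receptive-field patches of ``input_grid``, one per neuron."""
    p = state.params
    input_grid = np.asarray(input_grid, dtype=float)
    if input_grid.shape != (p.input_size, p.input_size):
        raise ValueError(
            f"input grid shape {input_grid.shape} does not match the field's "
            f"input sheet ({p.input_size}, {p.input_size})")
    return input_grid.ravel()[state.patch_idx]


def afferent_response(state: FieldState, params: FieldParams, input_grid: np.ndarray) -> np.ndarray:
    """Feedforward drive ``S_ij = sigma(gamma_aff * <W_ij, X_ij>)`` as a grid."""
    X = extract_patches(state, input_grid)
    s = params.gamma_aff * np.einsum("ni,ni->n", state.W_aff, X)
    return sigma(s, params.sigma_lo, params.sigma_hi).reshape(params.dim, params.dim)


def settle(state: FieldState, params: FieldParams, S: np.ndarray,
           eta0: np.ndarray | None = None, steps: int | None = None) -> np.ndarray:
    """Iterate the lateral dynamics ``settling_steps`` times at fixed drive.

    ``eta(s) = sigma(S + gamma_exc * sum_kl E[kl->ij] eta_kl(s-1)
    - gamma_inhb * sum_kl I[kl->ij] eta_kl(s-1))``. The iteration starts
    from ``eta0`` — by default the previous frame's settled activity
    (``state.eta_prev``; zero right after a sequence reset), which is how
    stimulus history enters the response. ``steps`` overrides the number
    of iterations (used when a surrounding loop drives settling one step
    at a time). Returns the settled grid; ``state`` is not modified.
    """
    S_flat = np.asarray(S, dtype=float).ravel()
    lo, hi = params.settle_thresholds
    eta = (state.eta_prev if eta0 is None else np.asarray(eta0, dtype=float)).ravel().copy()
    ge, gi = params.gamma_exc, params.gamma_inhb
    d = params.settle_damping
    for _ in range(params.settling_steps if steps is None else steps):
        e = np.einsum("nk,nk->n", state.W_exc, eta[state.exc_idx])
        i = np.einsum("nk,nk->n", state.W_inhb, eta[state.inhb_idx])
        target = sigma(S_flat + ge * e - gi * i, lo, hi)
        eta = target if d == 1.0 else (1.0 - d) * eta + d * target
    return eta.reshape(params.dim, params.dim)


def reset_activity(state: FieldState) -> FieldState:
    """Zero both activity grids (start of a new sequence); idempotent."""
    state.eta = np.zeros((state.params.dim, state.params.dim))
    state.eta_prev = np.zeros((state.params.dim, state.params.dim))
    return state
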