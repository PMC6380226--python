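import numpy as np
import pytest

from nfmotion.field import FieldParams, init_state


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_params():
    """3x3 field over a 4x4 input sheet, small radii, default sigmoid."""
    return FieldParams(dim=3, rf=2, input_size=4, stride=1, r_exc=1.0, r_inhb=2.0,
                      gamma_aff=1.0, gamma_exc=0.8, gamma_inhb=0.5, settling_steps=2)


@pytest.fixture
def tiny_state(tiny_params, rng):
    return init_state(tiny_params, rng)


def naive_afferent(state, params, input_grid):
    """Per-neuron double loop over the receptive-field inner product."""
    from nfmotion.field import sigma
    grid = np.asarray(input_grid, dtype=float)
    off = params.rf_offsets()
    S = np.zeros((params.dim, params.dim))
    for i in range(params.dim):
        for j in range(params.dim):
            n = i * params.dim + j
            acc = 0.0
            for a in range(params.rf):
                for b in range(params.rf):
                    acc += state.W_aff[n, a * params.rf + b] * grid[off[i] + a, off[j] + b]
            S[i, j] = sigma(params.gamma_aff * acc, params.sigma_lo, params.sigma_hi)
    return S


def naive_settle(state, params, S, eta0, steps=None):
    """Nested-loop settling over the dense lateral matrices."""
    from nfmotion.field import sigma
    n = params.n_neurons
    E = state.W_exc_dense()
    I = state.W_inhb_dense()
    lo, hi = params.settle_thresholds
    eta = np.asarray(eta0, dtype=float).ravel().copy()
    S_flat = np.asarray(S, dtype=float).ravel()
    d = params.settle_damping
    for _ in range(params.settling_steps if steps is None else steps):
        new = np.empty(n)
        for i in range(n):
            exc = sum(E[i, k] * eta[k] for k in range(n))
            inh = sum(I[i, k] * eta[k] for k in range(n))
            new[i] = sigma(S_flat[i] + params.gamma_exc * exc - params.gamma_inhb * inh, lo, hi)
        eta = new if d == 1.0 else (1.0 - d) * eta + d * new
    return eta.reshape(params.dim, params.dim)


def naive_frame_update(state, params, rule, input_grid, eta_t):
    """Loop composition of the three delta rules plus per-row normalization.

    Returns dense (W_aff, W_exc, W_inhb) after one frame update.
    """
    from nfmotion.field import extract_patches
    n = params.n_neurons
    eta = np.asarray(eta_t, dtype=float).ravel()
    eta_prev = state.eta_prev.ravel()
    W_aff = state.W_aff.copy()
    E = state.W_exc_dense()
    I = state.W_inhb_dense()
    exc_support = state._dense(state.exc_valid.astype(float), state.exc_idx, state.exc_valid) > 0
    inhb_support = state._dense(state.inhb_valid.astype(float), state.inhb_idx, state.inhb_valid) > 0

    if not (rule.freeze_afferent or state.afferent_frozen):
        X = extract_patches(state, input_grid)
        for i in range(n):
            for u in range(X.shape[1]):
                W_aff[i, u] += params.alpha_aff * X[i, u] * eta[i]
            s = W_aff[i].sum()
            if s > 0:
                W_aff[i] /= s

    for W, sup, alpha in ((E, exc_support, params.alpha_exc), (I, inhb_support, params.alpha_inhb)):
        for i in range(n):
            for k in range(n):
                if not sup[i, k]:
                    continue
                if rule.mode == "asymmetric":
                    W[i, k] += alpha * max(0.0, eta[i] - eta_prev[i]) * eta_prev[k]
                else:
                    W[i, k] += alpha * eta[i] * eta[k]
            s = W[i].sum()
            if s > 0:
                W[i] /= s
    return W_aff, E, I
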