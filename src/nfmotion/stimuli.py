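"""Synthetic moving-stimulus generators.

All stimuli are short sequences of H x W intensity frames in [0, 1]:
moving bars, step edges, drifting sinusoidal gratings, plaids (two
superimposed orthogonal gratings), translating solid squares, and
translating random-dot fields, plus salt-and-pepper / Gaussian noise
perturbations used in the robustness experiments.

Coordinate convention (used throughout the package): frames are row-major
arrays; x = column index increasing rightward, y increasing *upward*
(decreasing row). Direction 0 deg is rightward motion, 90 deg upward,
measured counter-clockwise. A bar is always oriented perpendicular to its
direction of motion, so a bar moving at 0 deg is vertical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as _Seq

import numpy as np

EIGHT_DIRECTIONS = (0, 45, 90, 135, 180, 225, 270, 315)
FOUR_DIRECTIONS = (0, 90, 180, 270)

#: Canonical edge motions: left-to-right, right-to-left, top-to-bottom, bottom-to-top.
EDGE_DIRECTIONS = {"L2R": 0, "R2L": 180, "T2B": 270, "B2T": 90}


@dataclass
class StimulusSequence:
    """An ordered stack of intensity frames with its motion label.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Intensity frames, values in [0, 1].
    direction_deg : float
        Direction of motion in degrees (0 = rightward, CCW positive).
    kind : str
        One of ``bar, edge, grating, plaid, square, rds_translate``.
    meta : dict
        Generator parameters (sizes, step, seed, plaid component
        directions, dot configuration id, ...).
    """

    frames: np.ndarray
    direction_deg: float
    kind: str
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def validate_sequence(seq: StimulusSequence) -> None:
    """Check the shared sequence invariants; raise ``ValueError`` on violation."""
    f = np.asarray(seq.frames)
    if f.ndim != 3:
        raise ValueError(f"frames must be a (n, H, W) stack, got ndim={f.ndim}")
    if not (np.isfinite(f).all() and f.min() >= 0.0 and f.max() <= 1.0):
        raise ValueError("frame values must lie in [0, 1]")


def _unit_vector(direction_deg: float) -> tuple[float, float]:
    """(row, col) displacement of a unit step along ``direction_deg``."""
    th = np.deg2rad(direction_deg)
    return -np.sin(th), np.cos(th)  # row decreases for upward motion


def _rasterize_rect(image_size: int, centre_rc: tuple[float, float],
                    length: float, width: float, orientation_rc: tuple[float, float]) -> np.ndarray:
    """Binary frame with a length x width rectangle centred at ``centre_rc``.

    ``orientation_rc`` is the unit vector of the long axis. Pixels are lit
    on half-open intervals [-length/2, length/2) x [-width/2, width/2) so an
    axis-aligned even-sized rectangle covers exactly length*width pixels.
    """
    rr, cc = np.meshgrid(np.arange(image_size), np.arange(image_size), indexing="ij")
    dr = rr - centre_rc[0]
    dc = cc - centre_rc[1]
    o_r, o_c = orientation_rc
    # perpendicular (short) axis
    p_r, p_c = -o_c, o_r
    u = dr * o_r + dc * o_c
    v = dr * p_r + dc * p_c
    lit = (u >= -length / 2) & (u < length / 2) & (v >= -width / 2) & (v < width / 2)
    return lit.astype(float)


def make_moving_bar(direction_deg: float, image_size: int = 64, bar_len: int = 30,
                    bar_width: int = 2, n_frames: int = 8, step_px: float = 7.8) -> StimulusSequence:
    """A white bar, perpendicular to its motion, translating across a black frame.

    The bar centre follows a floating-point trajectory symmetric about the
    image centre with displacement ``step_px`` per frame; each frame is
    rasterized by nearest-pixel (half-open interval) coverage.
    """
    if direction_deg not in EIGHT_DIRECTIONS:
        raise ValueError(f"direction_deg must be one of {EIGHT_DIRECTIONS}, got {direction_deg}")
    if bar_len > image_size:
        raise ValueError(f"bar_len={bar_len} exceeds image_size={image_size}")
    m_r, m_c = _unit_vector(direction_deg)
    o_r, o_c = -m_c, m_r  # bar long axis perpendicular to motion
    c0 = (image_size - 1) / 2.0
    frames = []
    for k in range(n_frames):
        t = k - (n_frames - 1) / 2.0
        centre = (c0 + t * step_px * m_r, c0 + t * step_px * m_c)
        frames.append(_rasterize_rect(image_size, centre, bar_len, bar_width, (o_r, o_c)))
    seq = StimulusSequence(np.stack(frames), float(direction_deg), "bar",
                           {"image_size": image_size, "bar_len": bar_len,
                            "bar_width": bar_width, "step_px": step_px})
    validate_sequence(seq)
    return seq


def make_moving_edge(direction: str, image_size: int = 64, n_frames: int = 64) -> StimulusSequence:
    """A step edge (filled half-plane) advancing one pixel per frame.

    ``direction`` is one of ``L2R, R2L, T2B, B2T``. For L2R, frame ``t``
    has exactly ``t`` fully lit columns (anchored at the left border);
    the other directions are its mirror/transpose.
    """
    if direction not in EDGE_DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(EDGE_DIRECTIONS)}, got {direction!r}")
    frames = np.zeros((n_frames, image_size, image_size))
    for t in range(n_frames):
        k = min(t, image_size)
        if k == 0:
            continue
        if direction == "L2R":
            frames[t, :, :k] = 1.0
        elif direction == "R2L":
            frames[t, :, image_size - k:] = 1.0
        elif direction == "T2B":
            frames[t, :k, :] = 1.0
        else:  # B2T
            frames[t, image_size - k:, :] = 1.0
    seq = StimulusSequence(frames, float(EDGE_DIRECTIONS[direction]), "edge",
                           {"image_size": image_size, "edge": direction})
    validate_sequence(seq)
    return seq


def make_moving_grating(direction_deg: float, spatial_period_px: float = 5.0,
                        image_size: int = 64, n_frames: int = 10,
                        speed_px: float = 1.0) -> StimulusSequence:
    """A sinusoidal grating drifting along ``direction_deg``.

    Luminance is a raised cosine of the coordinate projected on the motion
    axis, with drift phase centred on the middle frame; with that
    convention the sequence for direction d + 180 deg is exactly the time
    reversal of the sequence for d.
    """
    if spatial_period_px <= 1:
        raise ValueError(f"spatial_period_px must exceed 1 px, got {spatial_period_px}")
    th = np.deg2rad(direction_deg)
    rr, cc = np.meshgrid(np.arange(image_size), np.arange(image_size), indexing="ij")
    proj = cc * np.cos(th) + (-rr) * np.sin(th)  # coordinate along motion axis
    frames = []
    for f in range(n_frames):
        phase = speed_px * (f - (n_frames - 1) / 2.0)
        frames.append(0.5 * (1.0 + np.cos(2 * np.pi * (proj - phase) / spatial_period_px)))
    seq = StimulusSequence(np.stack(frames), float(direction_deg), "grating",
                           {"image_size": image_size, "spatial_period_px": spatial_period_px,
                            "speed_px": speed_px})
    validate_sequence(seq)
    return seq


def make_moving_plaid(pattern_direction_deg: float, spatial_period_px: float = 5.0,
                      image_size: int = 64, n_frames: int = 10,
                      speed_px: float = 1.0) -> StimulusSequence:
    """Two orthogonal gratings (pattern direction +/- 45 deg) superimposed.

    The plaid is the mean of its two component gratings (same period and
    speed), which keeps values in [0, 1]; its perceptually coherent
    motion is along ``pattern_direction_deg``.
    """
    comp = [(pattern_direction_deg - 45) % 360, (pattern_direction_deg + 45) % 360]
    g = [make_moving_grating(d, spatial_period_px, image_size, n_frames, speed_px) for d in comp]
    frames = 0.5 * (g[0].frames + g[1].frames)  # mean superposition stays in [0, 1]
    seq = StimulusSequence(frames, float(pattern_direction_deg), "plaid",
                           {"image_size": image_size, "spatial_period_px": spatial_period_px,
                            "speed_px": speed_px, "component_directions": comp})
    validate_sequence(seq)
    return seq


def make_moving_square(direction_deg: float, square_size: int = 24, image_size: int = 64,
                       n_frames: int = 5, step_px: float = 5.0) -> StimulusSequence:
    """A white square translating along ``direction_deg`` through the image centre.

    The trajectory is centred on the image centre so that the middle frame
    passes through it; the start position therefore differs per direction,
    and the square stays fully inside the frame.
    """
    if direction_deg not in EIGHT_DIRECTIONS:
        raise ValueError(f"direction_deg must be one of {EIGHT_DIRECTIONS}, got {direction_deg}")
    if square_size > image_size:
        raise ValueError("square does not fit in the frame")
    m_r, m_c = _unit_vector(direction_deg)
    c0 = (image_size - 1) / 2.0
    frames = []
    for k in range(n_frames):
        t = k - (n_frames - 1) / 2.0
        centre = (c0 + t * step_px * m_r, c0 + t * step_px * m_c)
        half = square_size / 2.0
        if not (centre[0] - half >= -0.5 and centre[0] + half <= image_size - 0.5
                and centre[1] - half >= -0.5 and centre[1] + half <= image_size - 0.5):
            raise ValueError("square leaves the frame; reduce step_px or n_frames")
        frames.append(_rasterize_rect(image_size, centre, square_size, square_size, (1.0, 0.0)))
    seq = StimulusSequence(np.stack(frames), float(direction_deg), "square",
                           {"image_size": image_size, "square_size": square_size,
                            "step_px": step_px})
    validate_sequence(seq)
    return seq


@dataclass
class DotConfiguration:
    """A random-dot placement: one dot per disjoint block of the grid.

    ``positions`` holds the top-left (row, col) of each ``dot_size`` x
    ``dot_size`` dot; every ``block_size`` x ``block_size`` tile of the
    ``grid_size`` x ``grid_size`` frame contains exactly one dot, placed
    uniformly at random fully inside its tile.
    """

    positions: np.ndarray  # (n_dots, 2) int
    grid_size: int = 32
    block_size: int = 8
    dot_size: int = 2
    seed: int | None = None

    def render(self) -> np.ndarray:
        frame = np.zeros((self.grid_size, self.grid_size))
        d = self.dot_size
        for r, c in self.positions:
            frame[r:r + d, c:c + d] = 1.0
        return frame


def make_rds_configuration(seed: int, grid_size: int = 32, block_size: int = 8,
                           dot_size: int = 2) -> DotConfiguration:
    """Place one dot uniformly at random inside each disjoint block.

    Deterministic for a given seed. Defaults: 16 dots of 2 x 2 px on a
    32 x 32 grid tiled into 16 blocks of 8 x 8.
    """
    if grid_size % block_size:
        raise ValueError("grid_size must be a multiple of block_size")
    rng = np.random.default_rng(seed)
    n_blocks = grid_size // block_size
    span = block_size - dot_size + 1  # top-left offsets keeping the dot inside its block
    positions = []
    for br in range(n_blocks):
        for bc in range(n_blocks):
            off = rng.integers(0, span, size=2)
            positions.append((br * block_size + off[0], bc * block_size + off[1]))
    return DotConfiguration(np.array(positions, dtype=int), grid_size, block_size, dot_size, seed)


def make_rds_translation(configuration: DotConfiguration, direction_deg: float,
                         n_frames: int = 5, step_px: int = 1) -> StimulusSequence:
    """Translate a dot configuration coherently with toroidal wrap-around.

    Every frame is the first frame circularly shifted by ``step_px`` per
    time step along ``direction_deg`` (cardinal directions only), so the
    dot density is conserved exactly.
    """
    if direction_deg not in FOUR_DIRECTIONS:
        raise ValueError(f"direction_deg must be one of {FOUR_DIRECTIONS}, got {direction_deg}")
    base = configuration.render()
    m_r, m_c = _unit_vector(direction_deg)
    frames = [np.roll(base, (round(t * step_px * m_r), round(t * step_px * m_c)), axis=(0, 1))
              for t in range(n_frames)]
    seq = StimulusSequence(np.stack(frames), float(direction_deg), "rds_translate",
                           {"grid_size": configuration.grid_size, "step_px": step_px,
                            "config_seed": configuration.seed})
    validate_sequence(seq)
    return seq


def add_salt_pepper_noise(sequence: StimulusSequence, density: float, seed: int) -> StimulusSequence:
    """Corrupt a ``density`` fraction of each frame's pixels to 0 or 1.

    Corrupted pixels are chosen uniformly at random and set to 0 (pepper)
    or 1 (salt) with equal probability, so on a black background roughly
    half of them are visible. For a fixed seed the corrupted pixel sets
    are nested across densities: raising the density corrupts further,
    previously clean pixels without re-randomizing the old ones — the
    incremental regime of a noise sweep.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    frames = sequence.frames.copy()
    n, h, w = frames.shape
    npix = h * w
    k = int(round(density * npix))
    rng = np.random.default_rng(seed)
    for i in range(n):
        # consume the same entropy regardless of density so selections nest
        values = rng.integers(0, 2, size=npix).astype(float)
        order = rng.permutation(npix)
        if k:
            flat = frames[i].ravel()
            flat[order[:k]] = values[order[:k]]
    out = StimulusSequence(frames, sequence.direction_deg, sequence.kind,
                           {**sequence.meta, "noise": "salt_pepper", "density": density,
                            "noise_seed": seed})
    validate_sequence(out)
    return out


def add_gaussian_noise(sequence: StimulusSequence, mean: float, variance: float,
                       seed: int) -> StimulusSequence:
    """Additive per-pixel Gaussian noise, clipped back to [0, 1]."""
    if variance < 0:
        raise ValueError(f"variance must be nonnegative, got {variance}")
    rng = np.random.default_rng(seed)
    noise = rng.normal(mean, np.sqrt(variance), size=sequence.frames.shape)
    frames = np.clip(sequence.frames + noise, 0.0, 1.0)
    out = StimulusSequence(frames, sequence.direction_deg, sequence.kind,
                           {**sequence.meta, "noise": "gaussian", "mean": mean,
                            "variance": variance, "noise_seed": seed})
    validate_sequence(out)
    return out


# ---------------------------------------------------------------------------
# Training-set builders (the counts used throughout the experiments)

def build_bar_set(bar_len: int = 30, **kw) -> list[StimulusSequence]:
    """The 8 moving-bar training sequences (one per direction, 8 frames each)."""
    return [make_moving_bar(d, bar_len=bar_len, **kw) for d in EIGHT_DIRECTIONS]


def build_grating_set(**kw) -> list[StimulusSequence]:
    """The 8 drifting-grating sequences (10 frames each)."""
    return [make_moving_grating(d, **kw) for d in EIGHT_DIRECTIONS]


def build_plaid_set(**kw) -> list[StimulusSequence]:
    """The 8 moving-plaid sequences (10 frames each)."""
    return [make_moving_plaid(d, **kw) for d in EIGHT_DIRECTIONS]


def build_square_set(**kw) -> list[StimulusSequence]:
    """The 8 moving-square sequences (5 frames each)."""
    return [make_moving_square(d, **kw) for d in EIGHT_DIRECTIONS]


def build_rds_sets(seed: int, n_configurations: int = 25, n_train_configurations: int = 20,
                   n_frames: int = 5) -> tuple[list[StimulusSequence], list[StimulusSequence]]:
    """Translational random-dot train/test sets, split by dot configuration.

    ``n_configurations`` seeded dot configurations are each translated in
    the four cardinal directions (5 frames, wrap-around), yielding
    ``4 * n_configurations`` sequences; the first
    ``n_train_configurations`` configurations form the training set and
    the remainder the test set (default 80/20 sequences).
    """
    rng = np.random.default_rng(seed)
    config_seeds = rng.integers(0, 2**31 - 1, size=n_configurations)
    train, test = [], []
    for i, cs in enumerate(config_seeds):
        cfg = make_rds_configuration(int(cs))
        dest = train if i < n_train_configurations else test
        for d in FOUR_DIRECTIONS:
            s = make_rds_translation(cfg, d, n_frames=n_frames)
            s.meta["configuration_index"] = i
            dest.append(s)
    return train, test
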