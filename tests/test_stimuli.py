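"""Stimulus generators: geometry, counts, symmetries, noise contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import nfmotion.stimuli as st


def column_com(frame):
    cols = np.arange(frame.shape[1])
    return (frame * cols[None, :]).sum() / frame.sum()


class TestMovingBar:
    def test_default_rightward_bar_is_vertical_30x2(self):
        seq = st.make_moving_bar(0)
        assert seq.frames.shape == (8, 64, 64)
        f0 = seq.frames[0]
        assert f0.sum() == 60  # 30 x 2 pixels
        rows = np.flatnonzero(f0.any(axis=1))
        cols = np.flatnonzero(f0.any(axis=0))
        assert rows.size == 30 and cols.size == 2

    def test_zero_step_freezes_the_bar(self):
        seq = st.make_moving_bar(90, step_px=0.0)
        assert all(np.array_equal(seq.frames[0], f) for f in seq.frames)

    def test_centroid_advances_by_step_within_rounding(self):
        seq = st.make_moving_bar(0)
        coms = [column_com(f) for f in seq.frames]
        shifts = np.diff(coms)
        assert np.all(np.abs(shifts - 7.8) <= 1.0)

    @pytest.mark.parametrize("bad", [10, 30.0001, -45, 360])
    def test_rejects_off_grid_directions(self, bad):
        with pytest.raises(ValueError):
            st.make_moving_bar(bad)

    def test_rejects_bar_longer_than_frame(self):
        with pytest.raises(ValueError):
            st.make_moving_bar(0, bar_len=65)


class TestMovingEdge:
    def test_left_to_right_lits_t_columns(self):
        seq = st.make_moving_edge("L2R")
        assert seq.frames.shape == (64, 64, 64)
        for t in (0, 1, 17, 63):
            frame = seq.frames[t]
            assert np.array_equal(frame[:, :t], np.ones((64, t)))
            assert frame[:, t:].sum() == 0

    def test_single_frame_edge_has_no_motion(self):
        seq = st.make_moving_edge("L2R", n_frames=1)
        assert seq.frames.shape[0] == 1 and seq.frames.sum() == 0

    def test_top_to_bottom_is_transpose_of_left_to_right(self):
        l2r = st.make_moving_edge("L2R")
        t2b = st.make_moving_edge("T2B")
        for a, b in zip(l2r.frames, t2b.frames):
            assert np.array_equal(b, a.T)


class TestGratingAndPlaid:
    def test_spatial_period_along_motion_axis(self):
        seq = st.make_moving_grating(0, spatial_period_px=5)
        row = seq.frames[0][0]
        # autocorrelation peaks at multiples of the 5 px period
        ac = np.correlate(row - row.mean(), row - row.mean(), mode="full")[row.size - 1:]
        assert ac[5] > 0.9 * ac[0]
        assert ac[2] < 0.2 * ac[0]

    def test_single_frame_stays_in_unit_range(self):
        seq = st.make_moving_grating(135, n_frames=1)
        assert seq.frames.min() >= 0 and seq.frames.max() <= 1

    @pytest.mark.parametrize("d", [0, 45, 90, 225])
    def test_opposite_direction_is_time_reversal(self, d):
        fwd = st.make_moving_grating(d)
        bwd = st.make_moving_grating((d + 180) % 360)
        assert np.allclose(fwd.frames, bwd.frames[::-1], atol=1e-12)

    def test_rejects_degenerate_period(self):
        with pytest.raises(ValueError):
            st.make_moving_grating(0, spatial_period_px=1.0)

    @pytest.mark.parametrize("pattern, components", [
        (45, {0.0, 90.0}),   # coherent motion of gratings at 0 and 90 deg
        (315, {270.0, 0.0}),
    ])
    def test_plaid_component_directions(self, pattern, components):
        seq = st.make_moving_plaid(pattern)
        assert set(seq.meta["component_directions"]) == components
        assert seq.frames.shape == (10, 64, 64)

    def test_superposing_a_grating_with_itself_is_identity(self):
        g = st.make_moving_grating(90)
        assert np.allclose(0.5 * (g.frames + g.frames), g.frames, atol=1e-12)


class TestMovingSquare:
    @pytest.mark.parametrize("d", [0, 45, 180, 315])
    def test_square_has_576_pixels_every_frame(self, d):
        seq = st.make_moving_square(d)
        assert seq.frames.shape[0] == 5
        assert all(f.sum() == 576 for f in seq.frames)

    def test_opposite_directions_are_time_reversals(self):
        fwd = st.make_moving_square(0)
        bwd = st.make_moving_square(180)
        assert np.allclose(fwd.frames, bwd.frames[::-1])


class TestRandomDots:
    def test_one_dot_per_block_and_64_lit_pixels(self):
        cfg = st.make_rds_configuration(7)
        frame = cfg.render()
        assert frame.sum() == 64  # 16 dots x 4 px
        for br in range(4):
            for bc in range(4):
                block = frame[br * 8:(br + 1) * 8, bc * 8:(bc + 1) * 8]
                assert block.sum() == 4

    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_configuration_deterministic_under_seed(self, seed):
        a = st.make_rds_configuration(seed)
        b = st.make_rds_configuration(seed)
        assert np.array_equal(a.positions, b.positions)

    def test_translation_conserves_dot_density(self):
        cfg = st.make_rds_configuration(3)
        seq = st.make_rds_translation(cfg, 90)
        counts = [f.sum() for f in seq.frames]
        assert counts == [64] * 5

    def test_frames_are_circular_shifts_of_frame_zero(self):
        cfg = st.make_rds_configuration(3)
        seq = st.make_rds_translation(cfg, 0)
        for t in range(5):
            assert np.array_equal(seq.frames[t], np.roll(seq.frames[0], t, axis=1))

    def test_torus_period_restores_initial_frame(self):
        cfg = st.make_rds_configuration(5)
        long = st.make_rds_translation(cfg, 270, n_frames=33)
        assert np.array_equal(long.frames[32], long.frames[0])


class TestNoise:
    def test_zero_density_is_identity(self):
        seq = st.make_moving_bar(0)
        noisy = st.add_salt_pepper_noise(seq, 0.0, seed=1)
        assert np.array_equal(noisy.frames, seq.frames)

    def test_density_002_changes_about_forty_pixels_on_black_frames(self):
        # on a near-black frame only the salt half of the corrupted pixels shows
        seq = st.make_moving_bar(0)
        noisy = st.add_salt_pepper_noise(seq, 0.02, seed=2)
        changed = [(noisy.frames[t] != seq.frames[t]).sum() for t in range(8)]
        assert 20 <= np.mean(changed) <= 60

    def test_full_density_saturates_to_binary(self):
        seq = st.make_moving_grating(0)
        noisy = st.add_salt_pepper_noise(seq, 1.0, seed=3)
        assert set(np.unique(noisy.frames)) <= {0.0, 1.0}

    def test_corrupted_sets_nest_across_densities(self):
        # the incremental sweep regime: raising density only corrupts more pixels
        seq = st.make_moving_bar(0)
        lo = st.add_salt_pepper_noise(seq, 0.05, seed=9)
        hi = st.add_salt_pepper_noise(seq, 0.10, seed=9)
        changed_lo = lo.frames != seq.frames
        changed_hi = hi.frames != seq.frames
        assert np.all(changed_hi | ~changed_lo)

    def test_gaussian_noise_bounded_and_matches_requested_variance(self):
        seq = st.make_moving_grating(0)
        var = 0.01
        noisy = st.add_gaussian_noise(seq, 0.0, var, seed=4)
        assert noisy.frames.min() >= 0 and noisy.frames.max() <= 1
        # pixels at least 3 sigma from the clip bounds are clipping-free
        interior = (seq.frames > 0.3) & (seq.frames < 0.7)
        resid = (noisy.frames - seq.frames)[interior]
        assert abs(resid.var() - var) < 0.05 * var

    def test_gaussian_zero_variance_is_identity(self):
        seq = st.make_moving_bar(45)
        noisy = st.add_gaussian_noise(seq, 0.0, 0.0, seed=5)
        assert np.array_equal(noisy.frames, seq.frames)


class TestSetBuilders:
    def test_training_set_counts(self):
        assert len(st.build_bar_set()) == 8
        assert len(st.build_grating_set()) == 8
        assert len(st.build_plaid_set()) == 8
        assert len(st.build_square_set()) == 8
        train, test = st.build_rds_sets(seed=0)
        assert len(train) == 80 and len(test) == 20

    def test_every_generated_sequence_validates(self):
        for seq in (st.build_bar_set() + st.build_plaid_set() + st.build_square_set()):
            st.validate_sequence(seq)
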