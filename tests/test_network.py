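"""Network assembly, presentation, layer-wise training, presets."""

import numpy as np
import pytest

from nfmotion.field import FieldParams, afferent_response, init_state, settle
from nfmotion.network import (LayeredNetwork, load_preset, present_sequence,
                              saturation_fraction, train_layer)
from nfmotion.plasticity import LearningRule
from nfmotion.stimuli import StimulusSequence, build_bar_set


def tiny_network(rng, n_fields=2):
    p1 = FieldParams(dim=3, rf=2, input_size=4, stride=1, r_exc=1, r_inhb=2,
                     gamma_exc=0.5, gamma_inhb=0.3, settling_steps=2, epochs=5)
    fields = [init_state(p1, rng)]
    rules = [LearningRule()]
    if n_fields == 2:
        p2 = FieldParams(dim=2, rf=2, input_size=3, stride=1, r_exc=1, r_inhb=2,
                         gamma_exc=0.4, gamma_inhb=0.2, settling_steps=2, epochs=5)
        fields.append(init_state(p2, rng))
        rules.append(LearningRule())
    return LayeredNetwork(4, fields, rules)


def random_sequence(rng, n_frames=3, size=4):
    return StimulusSequence(rng.uniform(size=(n_frames, size, size)), 0.0, "bar")


class TestWiring:
    def test_rejects_inconsistent_geometry_chain(self, rng):
        p1 = FieldParams(dim=3, rf=2, input_size=4, stride=1, r_exc=1, r_inhb=2)
        p2 = FieldParams(dim=3, rf=2, input_size=4, stride=1, r_exc=1, r_inhb=2)
        with pytest.raises(ValueError, match="input sheet"):
            LayeredNetwork(4, [init_state(p1, rng), init_state(p2, rng)],
                           [LearningRule(), LearningRule()])


class TestPresentSequence:
    def test_no_learning_leaves_weights_bit_identical(self, rng):
        net = tiny_network(rng)
        before = [(f.W_aff.copy(), f.W_exc.copy(), f.W_inhb.copy()) for f in net.fields]
        present_sequence(net, random_sequence(rng), learn=False)
        for f, (wa, we, wi) in zip(net.fields, before):
            assert np.array_equal(f.W_aff, wa)
            assert np.array_equal(f.W_exc, we)
            assert np.array_equal(f.W_inhb, wi)

    def test_single_frame_sequence_triggers_no_lateral_learning(self, rng):
        # after the reset the presynaptic factor of the asymmetric rule is zero
        net = tiny_network(rng, n_fields=1)
        we = net.fields[0].W_exc.copy()
        wi = net.fields[0].W_inhb.copy()
        present_sequence(net, random_sequence(rng, n_frames=1), learn=True, train_index=0)
        assert np.allclose(net.fields[0].W_exc, we, atol=1e-12)
        assert np.allclose(net.fields[0].W_inhb, wi, atol=1e-12)

    def test_activity_chain_matches_hand_composed_lockstep(self, rng):
        net = tiny_network(rng)
        seq = random_sequence(rng)
        hist = present_sequence(net, seq, learn=False)
        # hand-roll the concurrent settling: one lateral step per field per tick
        etas = [np.zeros((3, 3)), np.zeros((2, 2))]
        for t, frame in enumerate(seq.frames):
            f0, f1 = net.fields
            S0 = afferent_response(f0, f0.params, frame)
            for _ in range(2):
                etas[0] = settle(f0, f0.params, S0, eta0=etas[0], steps=1)
                S1 = afferent_response(f1, f1.params, etas[0])
                etas[1] = settle(f1, f1.params, S1, eta0=etas[1], steps=1)
            assert np.allclose(hist[0][t], etas[0], atol=1e-12)
            assert np.allclose(hist[1][t], etas[1], atol=1e-12)

    def test_history_shapes(self, rng):
        net = tiny_network(rng)
        hist = present_sequence(net, random_sequence(rng, n_frames=3))
        assert hist[0].shape == (3, 3, 3) and hist[1].shape == (3, 2, 2)


class TestSaturationFraction:
    def test_all_zero_deltas_are_fully_saturated(self):
        assert saturation_fraction(np.zeros(10), 1e-6) == 1.0

    def test_no_deltas_below_epsilon(self):
        assert saturation_fraction(np.ones(5), 0.5) == 0.0

    def test_partial_count(self):
        assert saturation_fraction(np.array([0.0, 0.0, 0.0, 1.0]), 0.5) == 0.75


class TestTrainLayer:
    def test_zero_epochs_change_nothing(self, rng):
        net = tiny_network(rng, n_fields=1)
        before = net.fields[0].W_aff.copy()
        report = train_layer(net, 0, [random_sequence(rng)], epochs=0, seed=0)
        assert report.epochs_run == 0
        assert np.array_equal(net.fields[0].W_aff, before)

    def test_all_zero_stimuli_leave_weights_unchanged(self, rng):
        net = tiny_network(rng, n_fields=1)
        zeros = StimulusSequence(np.zeros((3, 4, 4)), 0.0, "bar")
        before = net.fields[0].W_aff.copy()
        train_layer(net, 0, [zeros], epochs=2, seed=0)
        assert np.allclose(net.fields[0].W_aff, before, atol=1e-12)

    def test_training_upper_layer_freezes_lower_weights(self, rng):
        net = tiny_network(rng)
        lower = (net.fields[0].W_aff.copy(), net.fields[0].W_exc.copy(),
                 net.fields[0].W_inhb.copy())
        train_layer(net, 1, [random_sequence(rng) for _ in range(2)], epochs=2, seed=0)
        assert np.array_equal(net.fields[0].W_aff, lower[0])
        assert np.array_equal(net.fields[0].W_exc, lower[1])
        assert np.array_equal(net.fields[0].W_inhb, lower[2])

    def test_identical_seeds_give_identical_weights(self):
        preset = load_preset("bar_v1")
        bars = build_bar_set()
        final = []
        for _ in range(2):
            net = preset.build_network(seed=5)
            train_layer(net, 0, bars, epochs=2, seed=5, saturation_target=2.0)
            final.append((net.fields[0].W_aff.copy(), net.fields[0].W_exc.copy()))
        assert np.array_equal(final[0][0], final[1][0])
        assert np.array_equal(final[0][1], final[1][1])

    def test_report_records_per_epoch_deltas(self, rng):
        net = tiny_network(rng, n_fields=1)
        report = train_layer(net, 0, [random_sequence(rng)], epochs=3, seed=1,
                             saturation_target=2.0)
        assert report.epochs_run == 3
        assert len(report.mean_abs_delta["excitatory"]) == 3
        assert len(report.saturation_trace) == 3
        assert all(0 <= s <= 1 for s in report.saturation_trace)


class TestPresets:
    @pytest.mark.parametrize("name, dims, rfs", [
        ("bar_v1", [20], [64]),
        ("grating_plaid", [20, 13], [24, 8]),
        ("square", [13, 15], [12, 13]),
        ("rds_translate", [29, 22], [4, 8]),
    ])
    def test_preset_geometry_matches_parameter_table(self, name, dims, rfs):
        net = load_preset(name).build_network(seed=0)
        assert [f.params.dim for f in net.fields] == dims
        assert [f.params.rf for f in net.fields] == rfs

    def test_bar_preset_scalars(self):
        f = load_preset("bar_v1").build_network(seed=0).fields[0].params
        assert (f.r_exc, f.r_inhb) == (3, 10)
        assert f.gamma_exc == 3.9
        assert f.settling_steps == 10 and f.epochs == 500

    def test_rds_preset_has_fixed_unit_afferents_and_reduced_gain(self):
        net = load_preset("rds_translate").build_network(seed=0)
        nf1 = net.fields[0]
        assert nf1.afferent_frozen
        assert np.all(nf1.W_aff == 1.0)
        assert nf1.params.gamma_aff == 0.3
        assert net.fields[1].params.gamma_exc == 15.68

    def test_unknown_preset_is_an_error(self):
        with pytest.raises(ValueError, match="unknown preset"):
            load_preset("nope")

    def test_rds_training_sets_split_by_configuration(self):
        sets = load_preset("rds_translate").training_sets(seed=1)
        assert len(sets["train"][0]) == 80 and len(sets["test"]) == 20
        train_cfg = {s.meta["configuration_index"] for s in sets["train"][0]}
        test_cfg = {s.meta["configuration_index"] for s in sets["test"]}
        assert train_cfg.isdisjoint(test_cfg)
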