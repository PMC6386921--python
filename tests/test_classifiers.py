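"""Classifier contracts: GAP, the motion-state net, and the group image nets."""

import dataclasses

import numpy as np
import pytest

from hierfusion.alignment import FramePayload
from hierfusion.classifiers import (
    ConvExtractor,
    PassthroughExtractor,
    TrainConfig,
    gap,
    train_group_frame_classifier,
    train_group_sequence_classifier,
    train_motion_classifier,
)
from hierfusion.classifiers import MotionStateClassifier
from hierfusion.synthetic import generate_dataset, preset

STATES = ("LY", "SD", "ST", "WK")


def segments_and_labels(data, label_attr="state"):
    return [s.segment for s in data], [getattr(s, label_attr) for s in data]


class TestGap:
    def test_hand_computed_two_map_example(self):
        maps = [[[1, 3], [5, 7]], [[0, 2], [4, 6]]]
        np.testing.assert_allclose(gap(maps), [4.0, 3.0])

    def test_constant_map_pools_to_its_value(self):
        maps = np.full((3, 5, 5), 7.5)
        np.testing.assert_allclose(gap(maps), [7.5, 7.5, 7.5])

    def test_1x1_maps_are_identity_on_channel_vector(self, rng):
        v = rng.standard_normal(12)
        np.testing.assert_allclose(gap(v.reshape(12, 1, 1)), v)

    def test_matches_brute_force_mean_on_random_tensors(self, rng):
        for _ in range(10):
            C, H, W = rng.integers(1, 6, size=3)
            maps = rng.standard_normal((C, H, W))
            expected = np.array([maps[c].sum() / (H * W) for c in range(C)])
            np.testing.assert_allclose(gap(maps), expected, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gap(np.empty((0, 2, 2)))


class TestTrainConfigDefaults:
    def test_published_hyperparameters_are_the_role_defaults(self):
        m = TrainConfig.motion_default()
        assert (m.lr, m.beta1, m.beta2) == (1e-3, 0.9, 0.99)
        assert (m.epochs, m.batch_size, m.hidden) == (150, 30, 128)
        h = TrainConfig.frame_head_default()
        assert (h.epochs, h.batch_size) == (50, 8)
        s = TrainConfig.sequence_default()
        assert (s.hidden, s.fc_width, s.dropout) == (512, 512, 0.7)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestMotionClassifier:
    def test_untrained_zero_head_is_uniform(self, ebutton_data):
        model = MotionStateClassifier(STATES, TrainConfig.motion_reduced())
        p = model.predict_proba(ebutton_data[0].segment)
        np.testing.assert_allclose(p, 0.25, atol=1e-12)

    def test_trained_state_accuracy_above_95_percent(self):
        spec = preset("ebutton-like", seed=7)
        data = generate_dataset(spec, 1000, seed=7)
        segs, labels = segments_and_labels(data[:800])
        model = train_motion_classifier(
            segs, labels, STATES, TrainConfig.motion_reduced(seed=7))
        X = np.stack([s.segment.samples for s in data[800:]])
        pred = [model.classes[i] for i in np.argmax(model.predict_proba_batch(X), axis=1)]
        acc = np.mean([p == s.state for p, s in zip(pred, data[800:])])
        assert acc > 0.95

    def test_output_is_a_probability_simplex(self, ebutton_data):
        segs, labels = segments_and_labels(ebutton_data[:200])
        model = train_motion_classifier(
            segs, labels, STATES,
            TrainConfig.motion_reduced(seed=1).__class__(
                epochs=2, batch_size=64, hidden=16, stride=3, seed=1))
        P = model.predict_proba_batch(np.stack([s.samples for s in segs[:50]]))
        assert np.all(P >= 0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_shuffled_labels_learn_nothing_beyond_chance(self, ebutton_data):
        rng = np.random.default_rng(0)
        segs, labels = segments_and_labels(ebutton_data[:600])
        shuffled = list(rng.permutation(labels))
        model = train_motion_classifier(
            segs[:500], shuffled[:500], STATES,
            TrainConfig(epochs=3, batch_size=64, hidden=16, stride=3, seed=0))
        X = np.stack([s.samples for s in segs[500:]])
        pred = [model.classes[i] for i in np.argmax(model.predict_proba_batch(X), axis=1)]
        acc = np.mean([p == t for p, t in zip(pred, shuffled[500:])])
        # label marginal is skewed (the sedentary state dominates), so the
        # best label-independent strategy is the majority class
        counts = [shuffled.count(s) / len(shuffled) for s in STATES]
        chance = max(counts)
        assert acc < chance + 3.3 * np.sqrt(chance * (1 - chance) / 100)

    def test_same_seed_gives_identical_parameters(self, ebutton_data):
        segs, labels = segments_and_labels(ebutton_data[:120])
        cfg = TrainConfig(epochs=2, batch_size=32, hidden=16, stride=3, seed=5)
        m1 = train_motion_classifier(segs, labels, STATES, cfg)
        m2 = train_motion_classifier(segs, labels, STATES, cfg)
        for k in m1.lstm.params:
            np.testing.assert_array_equal(m1.lstm.params[k], m2.lstm.params[k])
        np.testing.assert_array_equal(m1.head.params["W"], m2.head.params["W"])

    def test_single_class_data_rejected(self, ebutton_data):
        segs = [s.segment for s in ebutton_data[:50]]
        with pytest.raises(ValueError, match="single class"):
            train_motion_classifier(segs, ["SD"] * 50, STATES,
                                    TrainConfig(epochs=1, seed=0))

    def test_segment_length_mismatch_rejected(self, ebutton_data):
        segs, labels = segments_and_labels(ebutton_data[:100])
        cfg = TrainConfig(epochs=1, batch_size=32, hidden=8, stride=3, seed=0)
        model = train_motion_classifier(segs, labels, STATES, cfg)
        with pytest.raises(ValueError, match="length"):
            model.predict_proba(np.zeros((100, 6)))


class TestGroupFrameClassifier:
    def test_high_separation_group_accuracy_above_90_percent(self, ebutton):
        spec = dataclasses.replace(preset("ebutton-like", seed=3), separation=3.0)
        data = generate_dataset(spec, 1600, seed=3)
        group = ebutton.invert("SD")  # 11 activities
        members = [s for s in data if s.activity in group][:1100]
        cut = 900
        model = train_group_frame_classifier(
            group, [s.payload for s in members[:cut]],
            [s.activity for s in members[:cut]],
            PassthroughExtractor(spec.feature_dim),
            TrainConfig.frame_head_reduced(seed=3))
        acc = np.mean([model.predict(s.payload) == s.activity
                       for s in members[cut:]])
        assert acc > 0.9

    def test_singleton_group_training_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            train_group_frame_classifier(
                ("WK-DS",), [], [], PassthroughExtractor(4), TrainConfig(seed=0))

    def test_label_outside_group_rejected(self, ebutton_data, ebutton_spec):
        group = ("NP", "TU")
        members = [s for s in ebutton_data if s.activity in group][:20]
        with pytest.raises(ValueError, match="outside"):
            train_group_frame_classifier(
                group, [s.payload for s in members],
                ["SW"] * len(members),
                PassthroughExtractor(ebutton_spec.feature_dim), TrainConfig(seed=0))

    def test_extractor_is_frozen_through_training(self, ebutton_data, ebutton, ebutton_spec):
        ext = ConvExtractor(in_channels=1, n_channels=8, seed=2)
        before = ext.checksum()
        group = ebutton.invert("LY")
        members = [s for s in ebutton_data if s.activity in group][:60]
        rng = np.random.default_rng(0)
        payloads = [FramePayload([0.0], images=rng.standard_normal((12, 12, 1)))
                    for _ in members]
        train_group_frame_classifier(
            group, payloads, [s.activity for s in members], ext,
            TrainConfig(epochs=2, batch_size=16, seed=0))
        assert ext.checksum() == before

    def test_sequence_payload_raises_type_error(self, ebutton_data, ebutton, ebutton_spec):
        group = ebutton.invert("LY")
        members = [s for s in ebutton_data if s.activity in group][:40]
        model = train_group_frame_classifier(
            group, [s.payload for s in members], [s.activity for s in members],
            PassthroughExtractor(ebutton_spec.feature_dim),
            TrainConfig(epochs=2, batch_size=16, seed=0))
        seq = FramePayload([0.0, 0.1], features=np.zeros((2, ebutton_spec.feature_dim)))
        with pytest.raises(TypeError, match="sequence"):
            model.predict_proba(seq)


@pytest.fixture(scope="module")
def highrate():
    spec = preset("multimodal-like", seed=11)
    return spec, generate_dataset(spec, 500, seed=11)


class TestGroupSequenceClassifier:

    def test_sequence_beats_single_frame_on_correlated_data(self, highrate):
        spec, data = highrate
        group = spec.correspondence.invert("SD/ST/CY")
        members = [s for s in data if s.activity in group]
        cut = int(0.8 * len(members))
        ext = PassthroughExtractor(spec.feature_dim)
        seq_model = train_group_sequence_classifier(
            group, [s.payload for s in members[:cut]],
            [s.activity for s in members[:cut]], ext,
            TrainConfig.sequence_reduced(seed=11))
        # single-frame comparison: same data, first frame only
        def first_frame(s):
            return FramePayload([s.payload.timestamps[0]], features=s.payload.features[0])
        frame_model = train_group_frame_classifier(
            group, [first_frame(s) for s in members[:cut]],
            [s.activity for s in members[:cut]], ext,
            TrainConfig.frame_head_reduced(seed=11))
        seq_acc = np.mean([seq_model.predict(s.payload) == s.activity
                           for s in members[cut:]])
        frame_acc = np.mean([frame_model.predict(first_frame(s)) == s.activity
                             for s in members[cut:]])
        assert seq_acc > frame_acc

    def test_constant_sequence_prediction_is_order_invariant_and_deterministic(self, highrate):
        spec, data = highrate
        group = spec.correspondence.invert("WK/WK-US")
        members = [s for s in data if s.activity in group]
        model = train_group_sequence_classifier(
            group, [s.payload for s in members],
            [s.activity for s in members],
            PassthroughExtractor(spec.feature_dim),
            TrainConfig(epochs=2, batch_size=32, hidden=16, fc_width=16, seed=1))
        frame = np.full(spec.feature_dim, 0.3)
        K = 12
        payload = FramePayload(np.arange(K) * 0.1, features=np.tile(frame, (K, 1)))
        p1 = model.predict_proba(payload)
        # repeated evaluation is deterministic (dropout off at inference)
        np.testing.assert_allclose(model.predict_proba(payload), p1, atol=1e-4)
        # permuting identical frames cannot change the prediction
        perm = np.random.default_rng(0).permutation(K)
        permuted = FramePayload(payload.timestamps, features=payload.features[perm])
        np.testing.assert_allclose(model.predict_proba(permuted), p1, atol=1e-4)
        # K = 1 degenerates to a single recurrent step and is still a simplex
        single = FramePayload([0.0], features=frame)
        assert model.predict_proba(single).sum() == pytest.approx(1.0, abs=1e-6)

    def test_output_sums_to_one(self, highrate):
        spec, data = highrate
        group = spec.correspondence.invert("WK/WK-US")
        members = [s for s in data if s.activity in group]
        model = train_group_sequence_classifier(
            group, [s.payload for s in members], [s.activity for s in members],
            PassthroughExtractor(spec.feature_dim),
            TrainConfig(epochs=2, batch_size=32, hidden=16, fc_width=16, seed=2))
        p = model.predict_proba(members[0].payload)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p >= 0)


def test_within_group_sensor_signal_carries_no_activity_information(ebutton_data, ebutton):
    """Activities sharing a motion state are sensor-indistinguishable.

    A sensor-only classifier restricted to one group's activities (on
    segments drawn in that group's state) must sit at within-group chance,
    while the same architecture separates the states themselves — the
    premise that motivates routing by motion state.
    """
    group = ebutton.invert("SD")
    members = [s for s in ebutton_data if s.state == "SD" and s.activity in group]
    cut = int(0.75 * len(members))
    cfg = TrainConfig(epochs=3, batch_size=64, hidden=16, stride=3, seed=0)
    model = train_motion_classifier(
        [s.segment for s in members[:cut]],
        [s.activity for s in members[:cut]], group, cfg)
    X = np.stack([s.segment.samples for s in members[cut:]])
    pred = [model.classes[i] for i in np.argmax(model.predict_proba_batch(X), axis=1)]
    acc = np.mean([p == s.activity for p, s in zip(pred, members[cut:])])
    chance = 1.0 / len(group)
    n = len(members) - cut
    assert abs(acc - chance) < 3.3 * np.sqrt(chance * (1 - chance) / n) + 0.02
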