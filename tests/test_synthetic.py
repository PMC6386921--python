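"""Generator structure: the separability premises, presets, and the oracle."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from hierfusion.hierarchy import build_correspondence, load_fixture
from hierfusion.synthetic import (
    GeneratorSpec,
    StateSignalModel,
    bayes_oracle,
    generate_dataset,
    generate_sequence_dataset,
    make_state_models,
    preset,
)


class TestDeterminism:
    def test_same_spec_and_seed_is_bitwise_identical(self, ebutton_spec):
        a = generate_dataset(ebutton_spec, 60, seed=9)
        b = generate_dataset(ebutton_spec, 60, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.segment.samples, y.segment.samples)
            np.testing.assert_array_equal(x.payload.features, y.payload.features)
            assert (x.activity, x.state) == (y.activity, y.state)

    def test_different_seed_differs(self, ebutton_spec):
        a = generate_dataset(ebutton_spec, 10, seed=1)
        b = generate_dataset(ebutton_spec, 10, seed=2)
        assert not np.array_equal(a[0].segment.samples, b[0].segment.samples)


class TestClassBalance:
    def test_activity_counts_within_multinomial_99_ci(self, ebutton_spec):
        n = 10000
        data = generate_dataset(ebutton_spec, n, seed=17)
        acts = ebutton_spec.activities
        counts = np.array([sum(s.activity == a for s in data) for a in acts])
        p = 1.0 / len(acts)
        sd = np.sqrt(n * p * (1 - p))
        # 99% per-class bound with Bonferroni over 15 classes
        z = stats.norm.ppf(1 - 0.01 / (2 * len(acts)))
        assert np.all(np.abs(counts - n * p) < z * sd)


class TestPremises:
    def test_within_group_segments_identically_distributed(self, ebutton_spec):
        """Two-sample KS on per-segment channel means across activities that
        share the sedentary state: must not reject at alpha = 0.01."""
        data = generate_dataset(ebutton_spec, 4000, seed=23)
        sd_samples = [s for s in data if s.state == "SD"]
        group = ebutton_spec.correspondence.invert("SD")
        by_act = {a: [s.segment.samples.mean(axis=0) for s in sd_samples
                      if s.activity == a] for a in group[:4]}
        acts = [a for a in by_act if len(by_act[a]) >= 30]
        assert len(acts) >= 2
        a, b = acts[0], acts[1]
        for ch in range(6):
            x = [m[ch] for m in by_act[a]]
            y = [m[ch] for m in by_act[b]]
            assert stats.ks_2samp(x, y).pvalue > 0.01

    def test_walking_segments_peak_at_configured_gait_frequency(self, ebutton_spec):
        model = ebutton_spec.state_models["WK"]
        data = generate_dataset(ebutton_spec, 300, seed=31)
        wk = next(s for s in data if s.state == "WK")
        # project acceleration onto the oscillation direction
        g = np.asarray(model.gravity)
        u = g / np.linalg.norm(g)
        signal = wk.segment.samples[:, :3] @ u
        freqs = np.fft.rfftfreq(len(signal), d=1.0 / ebutton_spec.fs)
        power = np.abs(np.fft.rfft(signal - signal.mean())) ** 2
        peak = freqs[np.argmax(power)]
        assert peak == pytest.approx(model.osc_freq, abs=0.2)

    def test_oracle_accuracy_increases_with_separation(self):
        base = preset("ebutton-like", seed=2)
        accs = []
        for delta in (0.3, 1.0, 3.0):
            spec = dataclasses.replace(base, separation=delta)
            data = generate_dataset(spec, 400, seed=2)
            acts = spec.activities
            acc = np.mean([
                acts[int(np.argmax(bayes_oracle(spec, s, modality="image")))]
                == s.activity for s in data])
            accs.append(acc)
        assert accs[0] < accs[1] < accs[2]

    def test_vanishing_separation_drives_oracle_to_chance(self):
        spec = dataclasses.replace(preset("ebutton-like", seed=4), separation=1e-6)
        data = generate_dataset(spec, 400, seed=4)
        acts = spec.activities
        acc = np.mean([
            acts[int(np.argmax(bayes_oracle(spec, s, modality="image")))]
            == s.activity for s in data])
        chance = 1.0 / len(acts)
        assert abs(acc - chance) < 3.3 * np.sqrt(chance * (1 - chance) / len(data))


class TestBayesOracle:
    def _two_cluster_spec(self, delta, d=1):
        C = build_correspondence(["A", "B"], ["M"], [("A", "M"), ("B", "M")])
        means = np.zeros((2, d))
        means[0, 0] = -delta / 2.0
        means[1, 0] = +delta / 2.0
        models = make_state_models(["M"])
        return GeneratorSpec(correspondence=C, state_models=models,
                             feature_dim=d, cluster_means=means, separation=delta)

    def test_equidistant_point_gives_half_half(self):
        spec = self._two_cluster_spec(2.0)
        data = generate_dataset(spec, 1, seed=0)
        s = data[0]
        s.payload.features[...] = 0.0  # exactly between the two cluster means
        post = bayes_oracle(spec, s, modality="image")
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)

    def test_point_at_cluster_mean_with_large_separation(self):
        spec = self._two_cluster_spec(20.0)
        s = generate_dataset(spec, 1, seed=0)[0]
        s.payload.features[...] = spec.means()[0]
        post = bayes_oracle(spec, s, modality="image")
        assert post[0] > 0.999

    def test_monte_carlo_accuracy_matches_phi_closed_form(self):
        """1-d symmetric two-cluster Bayes accuracy is Phi(delta/2)."""
        delta = 1.5
        spec = self._two_cluster_spec(delta)
        data = generate_dataset(spec, 4000, seed=6)
        acts = spec.activities
        acc = np.mean([
            acts[int(np.argmax(bayes_oracle(spec, s, modality="image")))]
            == s.activity for s in data])
        expected = stats.norm.cdf(delta / 2.0)
        assert acc == pytest.approx(expected, abs=0.025)


class TestPresets:
    def test_ebutton_preset_uses_the_published_hierarchy(self, ebutton_spec):
        assert ebutton_spec.correspondence.fingerprint() == \
            load_fixture("eButton").fingerprint()
        assert ebutton_spec.regime == "low"
        assert ebutton_spec.fs == 90.0 and ebutton_spec.t_w == 3.0
        assert ebutton_spec.frame_spacing >= 4.0

    @pytest.mark.parametrize("name,m", [("multimodal-m5", 5), ("multimodal-m6", 6),
                                        ("multimodal-m7", 7), ("multimodal-m8", 8)])
    def test_multimodal_presets_validate(self, name, m):
        spec = preset(name)
        assert spec.correspondence.state_set.m == m
        assert spec.regime == "high" and spec.K == 90

    def test_200_sequences_yield_3000_overlapping_windows(self):
        spec = preset("multimodal-like", seed=8)
        samples, seq_ids = generate_sequence_dataset(spec, 200, seed=8)
        assert len(samples) == 3000
        assert len(set(seq_ids)) == 200
        # interior windows carry ~90 correlated frames (t_w * 30 fps)
        interior = [s for s in samples if not s.segment.pad_flags.any()]
        assert {s.payload.n_frames for s in interior} == {90}

    def test_invalid_specs_rejected(self, ebutton):
        models = make_state_models(ebutton.state_set.labels)
        with pytest.raises(ValueError, match="regime"):
            GeneratorSpec(ebutton, models, regime="medium")
        with pytest.raises(ValueError, match="rho"):
            GeneratorSpec(ebutton, models, rho=1.0)
        with pytest.raises(ValueError, match="signal model"):
            GeneratorSpec(ebutton, {"LY": models["LY"]})
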