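"""Generator semantics: class signatures, shifts, determinism, calibration."""

import numpy as np
import pytest

from aardapt import synthetic as sy
from aardapt.uda import mk_mmd


def static_model(noise_sd=0.0, gravity=(0.0, 0.0, 1.0)):
    return sy.ActivityModel("static", gravity, noise_sd=noise_sd)


def dynamic_model(freq, noise_sd=0.0, amp=(0.4, 50.0)):
    return sy.ActivityModel("dyn", (0.0, 0.0, 1.0), osc_frequency_hz=freq,
                            osc_amplitude=amp, noise_sd=noise_sd)


class TestSynthesizeWindow:
    def test_noise_free_static_is_constant_gravity(self, rng):
        w = sy.synthesize_window(static_model(), rng=rng)
        assert w.x.shape == (6, 200)
        np.testing.assert_array_equal(w.x[:3], np.tile([[0.0], [0.0], [1.0]], 200))
        np.testing.assert_array_equal(w.x[3:], 0.0)

    def test_integer_cycles_average_to_dc(self, rng):
        # 3 Hz over 2 s = 6 full periods, so channel means equal the DC term
        w = sy.synthesize_window(dynamic_model(3.0), rng=rng)
        np.testing.assert_allclose(w.x[:3].mean(axis=1), [0.0, 0.0, 1.0],
                                   atol=1e-9)
        np.testing.assert_allclose(w.x[3:].mean(axis=1), 0.0, atol=1e-9)

    @pytest.mark.parametrize("freq", [1.5, 3.0])
    def test_dominant_fft_peak_at_model_frequency(self, freq):
        rng = np.random.default_rng(7)
        hits = 0
        freqs = np.fft.rfftfreq(200, d=0.01)
        for _ in range(100):
            w = sy.synthesize_window(dynamic_model(freq, noise_sd=0.01), rng=rng)
            spectrum = np.abs(np.fft.rfft(w.x[0] - w.x[0].mean()))
            hits += freqs[spectrum.argmax()] == pytest.approx(freq, abs=0.26)
        assert hits >= 99

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="unit 3-vector"):
            sy.ActivityModel("bad", (0.0, 0.0, 2.0))
        with pytest.raises(ValueError, match="finite"):
            sy.ActivityModel("bad", (0.0, 0.0, 1.0), noise_sd=np.nan)
        with pytest.raises(ValueError, match="zero amplitude"):
            sy.ActivityModel("bad", (0.0, 0.0, 1.0), osc_amplitude=(0.1, 1.0))
        with pytest.raises(ValueError, match="Nyquist"):
            sy.synthesize_window(dynamic_model(60.0), fs_hz=100.0)

    def test_per_window_jitter_varies_posture_and_vigour(self):
        model = sy.ActivityModel("j", (0.0, 0.0, 1.0), osc_frequency_hz=2.0,
                                 osc_amplitude=(0.4, 50.0), noise_sd=0.0,
                                 orientation_jitter_deg=8.0,
                                 amplitude_jitter=0.25)
        rng = np.random.default_rng(0)
        w1 = sy.synthesize_window(model, rng=rng)
        w2 = sy.synthesize_window(model, rng=rng)
        # orientation jitter moves the gravity DC term between windows
        assert np.abs(w1.x[:3].mean(axis=1) - w2.x[:3].mean(axis=1)).max() > 1e-3
        with pytest.raises(ValueError, match="nonnegative"):
            sy.ActivityModel("bad", (0.0, 0.0, 1.0), amplitude_jitter=-0.1)

    def test_bursts_add_energy(self):
        calm = sy.ActivityModel("a", (0, 0, 1.0), noise_sd=0.05)
        bursty = sy.ActivityModel("b", (0, 0, 1.0), noise_sd=0.05, burst_prob=1.0)
        var_calm = np.var(sy.synthesize_window(
            calm, rng=np.random.default_rng(0)).x[0])
        var_bursty = np.var(sy.synthesize_window(
            bursty, rng=np.random.default_rng(0)).x[0])
        assert var_bursty > 2 * var_calm


class TestApplyShift:
    def test_identity_shift_is_exact(self, rng):
        w = sy.synthesize_window(dynamic_model(2.0, noise_sd=0.05), rng=rng)
        out = sy.apply_shift(w, sy.ShiftSpec.identity())
        np.testing.assert_array_equal(out.x, w.x)

    def test_90_degree_rotation_permutes_axes(self):
        w = sy.synthesize_window(static_model(gravity=(1.0, 0.0, 0.0)),
                                 rng=np.random.default_rng(0))
        spec = sy.ShiftSpec(rotation=sy.rotation_matrix((0, 0, 1.0), 90.0))
        out = sy.apply_shift(w, spec)
        np.testing.assert_allclose(out.x[:3], np.tile([[0.0], [1.0], [0.0]], 200),
                                   atol=1e-12)

    def test_gain_quadruples_variance_of_one_channel(self, rng):
        w = sy.synthesize_window(dynamic_model(2.0, noise_sd=0.05), rng=rng)
        gain = np.ones(6)
        gain[1] = 2.0
        out = sy.apply_shift(w, sy.ShiftSpec(channel_gain=gain))
        before = w.x.var(axis=1)
        after = out.x.var(axis=1)
        assert after[1] == pytest.approx(4 * before[1], rel=1e-9)
        np.testing.assert_allclose(after[[0, 2, 3, 4, 5]],
                                   before[[0, 2, 3, 4, 5]], rtol=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            sy.ShiftSpec(rotation=np.eye(3) * 1.5)
        with pytest.raises(ValueError, match="orthonormal"):
            sy.ShiftSpec(rotation=np.diag([1.0, 1.0, -1.0]))  # det -1


class TestGenerateDomainPair:
    def test_counts_and_labels(self, dog_models):
        cfg = sy.SyntheticConfig(class_models=tuple(dog_models),
                                 samples_per_class=50, seed=0)
        src, tgt = sy.generate_domain_pair(cfg, sy.shift_preset("species"))
        for ds in (src, tgt):
            assert len(ds) == 300
            assert set(ds.class_counts().values()) == {50}
            assert ds.window_length == 200

    def test_bit_identical_regeneration(self, dog_models):
        cfg = sy.SyntheticConfig(class_models=tuple(dog_models),
                                 samples_per_class=5, seed=42)
        a = sy.generate_domain_pair(cfg, sy.shift_preset("size"))
        b = sy.generate_domain_pair(cfg, sy.shift_preset("size"))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.X, y.X)
            np.testing.assert_array_equal(x.y, y.y)

    def test_adding_a_class_preserves_existing_draws(self, dog_models):
        cfg5 = sy.SyntheticConfig(class_models=tuple(dog_models[:5]),
                                  samples_per_class=4, seed=9)
        cfg6 = sy.SyntheticConfig(class_models=tuple(dog_models),
                                  samples_per_class=4, seed=9)
        src5, _ = sy.generate_domain_pair(cfg5, sy.ShiftSpec.identity())
        src6, _ = sy.generate_domain_pair(cfg6, sy.ShiftSpec.identity())
        np.testing.assert_array_equal(src5.X, src6.X[:len(src5)])

    def test_species_shift_raises_mmd_above_identity(self, dog_models):
        walking = [m for m in dog_models if m.class_name == "walking"]
        wins = 0
        for seed in range(20):
            cfg = sy.SyntheticConfig(class_models=tuple(walking),
                                     samples_per_class=12, seed=seed)
            s_id, t_id = sy.generate_domain_pair(cfg, sy.ShiftSpec.identity())
            s_sp, t_sp = sy.generate_domain_pair(cfg, sy.shift_preset("species"))
            flat = lambda d: d.X.reshape(len(d), -1)
            mmd_id = mk_mmd(flat(s_id), flat(t_id)).item()
            mmd_sp = mk_mmd(flat(s_sp), flat(t_sp)).item()
            wins += (mmd_sp > 0) and (mmd_sp > mmd_id)
        assert wins == 20

    def test_rotation_angle_mmd_monotone_on_average(self, dog_models):
        standing = [m for m in dog_models if m.class_name == "standing"]
        angles = [0.0, 30.0, 60.0, 90.0]
        means = []
        for angle in angles:
            spec = (sy.ShiftSpec.identity() if angle == 0.0 else
                    sy.ShiftSpec(rotation=sy.rotation_matrix((1.0, 0, 0), angle)))
            vals = []
            for seed in range(10):
                cfg = sy.SyntheticConfig(class_models=tuple(standing),
                                         samples_per_class=12, seed=seed)
                s, t = sy.generate_domain_pair(cfg, spec)
                vals.append(mk_mmd(s.X.reshape(len(s), -1),
                                   t.X.reshape(len(t), -1)).item())
            means.append(np.mean(vals))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_frequency_scaling_applies_at_generation_time(self):
        trot = dynamic_model(3.3, noise_sd=0.05, amp=(0.7, 120.0))
        cfg = sy.SyntheticConfig(class_models=(trot,), samples_per_class=3,
                                 seed=1)
        spec = sy.ShiftSpec(frequency_scale=0.5)
        _, tgt = sy.generate_domain_pair(cfg, spec)
        freqs = np.fft.rfftfreq(200, d=0.01)
        spectrum = np.abs(np.fft.rfft(tgt.X[0, 0] - tgt.X[0, 0].mean()))
        # 3.3 Hz scaled by 0.5 -> nearest bin of 1.65 Hz
        assert freqs[spectrum.argmax()] == pytest.approx(1.65, abs=0.26)


def test_identity_pair_passes_two_sample_check(dog_models):
    rejections = 0
    for seed in range(30):
        cfg = sy.SyntheticConfig(class_models=tuple(dog_models),
                                 samples_per_class=20, seed=seed)
        src, tgt = sy.generate_domain_pair(cfg, sy.ShiftSpec.identity())
        if sy.two_sample_channel_mean_test(src.X, tgt.X) < 0.01:
            rejections += 1
    assert rejections <= 2


def test_stream_frame_bookkeeping(dog_models):
    plan = [("walking", 3.0), ("", 0.5), ("standing", 2.0)]
    samples, epochs = sy.synthesize_stream_frame(
        dog_models, plan, rng=np.random.default_rng(0))
    assert samples.shape == (550, 6)
    assert epochs == [(0, 300, "walking"), (350, 550, "standing")]


def test_shift_preset_names():
    for name in ("sensor_position", "size", "gender", "species"):
        assert isinstance(sy.shift_preset(name), sy.ShiftSpec)
    with pytest.raises(KeyError):
        sy.shift_preset("teleportation")
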