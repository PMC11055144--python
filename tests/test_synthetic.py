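"""Properties of the seeded motion generator."""

import numpy as np
import pytest

import actimage as ai


class TestSessionGeneration:
    def test_single_repetition_yields_one_segment(self, templates):
        cfg = ai.ProtocolConfig(n_subjects=1, n_actions=1, n_repetitions=1, seed=0)
        _, metas = ai.generate_session(templates["A1"], cfg, "T1", seed=4)
        assert len(metas) == 1

    def test_same_seed_bitwise_identical(self, templates, small_config):
        p1, m1 = ai.generate_session(templates["A3"], small_config, "T1", seed=99)
        p2, m2 = ai.generate_session(templates["A3"], small_config, "T1", seed=99)
        assert np.array_equal(p1.values, p2.values)
        assert m1 == m2

    def test_session_layout_rest_between_reps(self, session_a6, small_config):
        profile, metas = session_a6
        n_rest = round(small_config.rest_duration * small_config.sample_rate)
        assert metas[0].start_frame == n_rest
        for a, b in zip(metas, metas[1:]):
            assert b.start_frame - a.end_frame == n_rest
        assert profile.n_frames - metas[-1].end_frame == n_rest

    @pytest.mark.parametrize("aid", [f"A{i}" for i in range(1, 17)])
    def test_velocity_matches_finite_difference(self, templates, aid):
        """Velocity channels are the analytic derivative of position:
        a central finite difference at 240 Hz agrees to 1e-3 m/s."""
        cfg = ai.ProtocolConfig(n_subjects=1, n_actions=16, n_repetitions=2, seed=0)
        profile, _ = ai.generate_session(templates[aid], cfg, "T1", seed=11)
        pos = profile.values[:, :, 0, :]
        vel = profile.values[:, :, 1, :]
        fd = np.gradient(pos, 1.0 / profile.sample_rate, axis=0)
        assert np.abs(fd[2:-2] - vel[2:-2]).max() <= 1e-3

    @pytest.mark.parametrize("aid", [f"A{i}" for i in range(1, 17)])
    def test_fast_interval_speed_elevated(self, templates, aid):
        """Within each repetition, mean end-effector speed inside the fast
        interval is at least speed_gain/2 times the mean outside it."""
        tpl = templates[aid]
        cfg = ai.ProtocolConfig(n_subjects=1, n_actions=16, n_repetitions=3, seed=0)
        profile, metas = ai.generate_session(tpl, cfg, "T1", seed=21)
        vrep = ai.representative_velocity(profile).values
        a, b = tpl.fast_interval
        for m in metas:
            seg = vrep[m.start_frame:m.end_frame]
            i0, i1 = int(a * len(seg)), int(b * len(seg))
            inside = seg[i0:i1].mean()
            outside = np.concatenate([seg[:i0], seg[i1:]]).mean()
            assert inside >= tpl.speed_gain / 2 * outside


class TestDatasetGeneration:
    @pytest.mark.parametrize(
        "subjects,actions,reps", [(1, 1, 1), (2, 3, 4)]
    )
    def test_segment_count_is_product(self, subjects, actions, reps):
        cfg = ai.ProtocolConfig(n_subjects=subjects, n_actions=actions,
                                n_repetitions=reps, seed=1)
        profiles, metas = ai.generate_dataset(cfg)
        assert len(profiles) == subjects * actions
        assert len(metas) == subjects * actions * reps

    def test_iter_sessions_matches_generate_dataset(self):
        cfg = ai.ProtocolConfig(n_subjects=2, n_actions=2, n_repetitions=2, seed=5)
        profiles, metas = ai.generate_dataset(cfg)
        streamed = list(ai.iter_sessions(cfg))
        assert len(streamed) == len(profiles)
        for (p_stream, _), p_mat in zip(streamed, profiles):
            assert np.array_equal(p_stream.values, p_mat.values)

    def test_rest_duration_must_be_positive(self):
        with pytest.raises(ai.ConfigurationError):
            ai.ProtocolConfig(rest_duration=0.0)

    def test_class_separability(self, templates):
        """Mean inter-class end-effector trajectory distance exceeds mean
        intra-class distance on a seeded batch (variability 0.05, no noise)."""
        cfg = ai.ProtocolConfig(n_subjects=3, n_actions=4, n_repetitions=2, seed=13)
        trajs, labels = [], []
        for profile, metas in ai.iter_sessions(cfg, templates):
            for m in metas:
                seg = profile.slice_frames(m.start_frame, m.end_frame)
                warped = ai.resample_profile(seg, 50)
                ee = [warped.joints.index(j) for j in ai.END_EFFECTORS]
                trajs.append(warped.values[:, ee, 0, :].ravel())
                labels.append(m.action_id)
        trajs = np.asarray(trajs)
        labels = np.asarray(labels)
        d = np.linalg.norm(trajs[:, None] - trajs[None, :], axis=2)
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        intra = d[same & off_diag].mean()
        inter = d[~same].mean()
        assert inter > intra


class TestNoise:
    def test_zero_pct_is_identity(self, segment_a6):
        noisy = ai.add_noise(segment_a6, 0.0, seed=1)
        assert np.array_equal(noisy.values, segment_a6.values)

    def test_same_seed_same_noise(self, segment_a6):
        a = ai.add_noise(segment_a6, 3.0, seed=42)
        b = ai.add_noise(segment_a6, 3.0, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_negative_pct_rejected(self, segment_a6):
        with pytest.raises(ai.ValidationError):
            ai.add_noise(segment_a6, -1.0, seed=0)

    def test_noise_sd_matches_rms_scaling(self, templates):
        """Empirical per-channel noise sd is within 5% of 0.03 x RMS on a
        long profile (moment-matching oracle)."""
        cfg = ai.ProtocolConfig(n_subjects=1, n_actions=1, n_repetitions=10, seed=2)
        profile, _ = ai.generate_session(templates["A6"], cfg, "T1", seed=3)
        noisy = ai.add_noise(profile, 3.0, seed=9)
        resid = noisy.values - profile.values
        rms = np.sqrt(np.mean(profile.values**2, axis=0))
        active = rms > 1e-6
        emp_sd = resid.std(axis=0)[active]
        target = 0.03 * rms[active]
        assert np.abs(emp_sd / target - 1).max() < 0.05


class TestTemplates:
    def test_sixteen_distinct_templates(self, templates):
        assert len(templates) == 16
        sigs = {
            (tpl.fast_interval, tuple(sorted(tpl.keyframes)))
            for tpl in templates.values()
        }
        assert len(sigs) == 16

    def test_near_duplicate_pair_differs_in_one_trajectory(self, templates):
        """A6 and A8 share the chamber keyframes; only the strike target
        (and hence the hand trajectory) differs."""
        a6, a8 = templates["A6"], templates["A8"]
        assert set(a6.keyframes) == set(a8.keyframes)
        kf6 = np.asarray([p for _, p in a6.keyframes["right_hand"]])
        kf8 = np.asarray([p for _, p in a8.keyframes["right_hand"]])
        assert np.allclose(kf6[1], kf8[1])      # same chamber
        assert not np.allclose(kf6[2], kf8[2])  # different target

    def test_yaml_roundtrip(self, templates, tmp_path):
        import yaml
        tpl = templates["A14"]
        path = tmp_path / "tpl.yaml"
        path.write_text(yaml.safe_dump(tpl.to_dict()))
        back = ai.ActionTemplate.from_dict(yaml.safe_load(path.read_text()))
        assert back.action_id == tpl.action_id
        assert back.fast_interval == tpl.fast_interval
        for joint in tpl.keyframes:
            for (p1, v1), (p2, v2) in zip(tpl.keyframes[joint], back.keyframes[joint]):
                assert p1 == p2 and np.allclose(v1, v2)
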