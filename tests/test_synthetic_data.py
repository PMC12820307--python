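"""Synthetic study generator: trajectories, kinematics, EMG synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kin2emg import emg_preprocess
from kin2emg.synthetic_data import (
    ArmModel,
    InvalidArgumentError,
    REST_POSE,
    StudyConfig,
    TaskSpec,
    _pose,
    base_emg_model,
    build_manifest,
    common_tasks,
    default_availability,
    default_task_catalog,
    forward_kinematics,
    generate_study,
    joint_trajectory,
    min_jerk_profile,
    synthesize_trial,
)


class TestMinJerk:
    def test_zero_displacement_is_constant(self):
        x = min_jerk_profile(0.0, 0.0, 1.0, 60)
        assert np.all(x == 0.0)

    def test_midpoint_symmetry(self):
        x = min_jerk_profile(0.0, 1.0, 1.0, 60)
        assert x[30] == pytest.approx(0.5, abs=1e-12)

    def test_peak_speed(self):
        # speed 30 tau^2 (1 - tau)^2 peaks at 1.875 for unit stroke/duration
        x = min_jerk_profile(0.0, 1.0, 1.0, 600)
        v = np.gradient(x, 1.0 / 600)
        assert v.max() == pytest.approx(1.875, rel=1e-4)
        assert np.argmax(v) == pytest.approx(300, abs=1)

    def test_velocity_zero_at_ends(self):
        x = min_jerk_profile(2.0, -1.0, 0.8, 200)
        v = np.diff(x) * 200
        assert abs(v[0]) < 5e-3 and abs(v[-1]) < 5e-3

    @pytest.mark.parametrize("duration,rate", [(0, 60), (-1, 60), (1, 0)])
    def test_invalid_arguments(self, duration, rate):
        with pytest.raises(InvalidArgumentError):
            min_jerk_profile(0, 1, duration, rate)


class TestForwardKinematics:
    def test_zero_pose_wrist_below_shoulder(self, arm):
        S, E, W, eef, q = forward_kinematics(arm, np.zeros(6))
        expected = arm.shoulder_origin - np.array(
            [0, 0, arm.upper_arm_length + arm.forearm_length]
        )
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_elbow_flexion_preserves_links(self, arm):
        q = np.zeros(6)
        q[3] = np.pi / 2
        S, E, W, eef, quat = forward_kinematics(arm, q)
        np.testing.assert_allclose(
            E, arm.shoulder_origin - [0, 0, arm.upper_arm_length], atol=1e-12
        )
        assert np.linalg.norm(W - E) == pytest.approx(arm.forearm_length, abs=1e-12)

    def test_horizontal_arm_points_sagittally(self, arm):
        q = np.zeros(6)
        q[1] = np.pi / 2
        S, E, W, eef, quat = forward_kinematics(arm, q)
        expected = arm.shoulder_origin + np.array(
            [arm.upper_arm_length + arm.forearm_length, 0, 0]
        )
        np.testing.assert_allclose(W, expected, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-2.5, 2.5), min_size=6, max_size=6))
    def test_rigid_link_conservation(self, angles):
        arm = ArmModel()
        S, E, W, eef, q = forward_kinematics(arm, np.array(angles))
        assert np.linalg.norm(E - S) == pytest.approx(arm.upper_arm_length, abs=1e-9)
        assert np.linalg.norm(W - E) == pytest.approx(arm.forearm_length, abs=1e-9)
        assert np.linalg.norm(q) == pytest.approx(1.0, abs=1e-9)

    def test_quaternion_sign_continuity(self, arm):
        t, q = joint_trajectory(default_task_catalog()[15], rate=60)
        _, _, _, _, quat = forward_kinematics(arm, q)
        dots = np.sum(quat[1:] * quat[:-1], axis=1)
        assert np.all(dots > 0)


class TestCatalog:
    def test_catalog_size_and_categories(self, catalog):
        assert len(catalog) == 23
        assert sum(t.category == "simple" for t in catalog) == 12
        assert sum(t.category == "complex" for t in catalog) == 11

    def test_availability_intersection(self):
        avail = default_availability()
        assert len(common_tasks(avail)) == 15

    def test_tasks_rest_bounded(self, catalog):
        for t in catalog:
            assert t.duration <= 7.5
            np.testing.assert_allclose(t.joint_waypoints[0], REST_POSE)
            np.testing.assert_allclose(t.joint_waypoints[-1], REST_POSE)

    def test_task_spec_rejects_non_rest_endpoints(self):
        with pytest.raises(InvalidArgumentError):
            TaskSpec("bad", "simple", (REST_POSE, _pose(el=1.0)), 3.0)

    def test_single_stroke_speed_is_unimodal(self, arm):
        stroke = TaskSpec(
            "stroke", "simple", (REST_POSE, _pose(el=np.pi / 2)), 2.0, out_and_back=False
        )
        t, q = joint_trajectory(stroke, rate=60)
        _, _, _, eef, _ = forward_kinematics(arm, q)
        speed = np.linalg.norm(np.gradient(eef, 1 / 60, axis=0), axis=1)
        peak = int(np.argmax(speed))
        eps = 1e-10
        assert np.all(np.diff(speed[:peak]) >= -eps)
        assert np.all(np.diff(speed[peak:]) <= eps)


class TestSynthesizeTrial:
    def test_seed_is_mandatory(self, arm, catalog, gt_model):
        with pytest.raises(InvalidArgumentError):
            synthesize_trial(arm, catalog[0], gt_model, seed=None)

    def test_zero_gains_zero_noise_gives_zero_emg(self, arm, catalog):
        gt = base_emg_model(baseline_noise_sd=0.0)
        gt.w_pos[:] = 0
        gt.w_neg[:] = 0
        gt.posture_gain[:] = 0
        trial = synthesize_trial(arm, catalog[0], gt, seed=1, joint_noise_sd=0.0)
        assert np.all(trial.raw_emg == 0)
        assert np.all(trial.gt_envelope == 0)

    def test_static_task_envelope_is_posture_only(self, arm, gt_model):
        hold = TaskSpec(
            "hold", "simple", (REST_POSE, REST_POSE + 1e-9, REST_POSE), 3.0
        )
        trial = synthesize_trial(
            arm,
            hold,
            gt_model,
            seed=2,
            amplitude_jitter_sd=0.0,
            duration_jitter_sd=0.0,
            joint_noise_sd=0.0,
        )
        posture = gt_model.posture_features(trial.joint_angles) @ gt_model.posture_gain.T
        np.testing.assert_allclose(
            trial.gt_envelope[30:-30], posture[30:-30] / gt_model.scale, atol=1e-6
        )

    def test_envelope_peak_tracks_joint_speed_peak(self, arm):
        gt = base_emg_model(baseline_noise_sd=0.0)
        gt.w_pos[:] = 0
        gt.w_neg[:] = 0
        gt.posture_gain[:] = 0
        gt.w_pos[3, 3] = 1.0  # biceps on elbow flexion velocity only
        gt.tau_act = 1e-3  # effectively no activation lag
        gt.scale = np.full(8, 2.5)  # keep the envelope away from the clip at 1
        stroke = TaskSpec(
            "flex", "simple", (REST_POSE, _pose(elbow=2.0)), 2.0, out_and_back=False
        )
        trial = synthesize_trial(
            arm,
            stroke,
            gt,
            seed=3,
            amplitude_jitter_sd=0.0,
            duration_jitter_sd=0.0,
            joint_noise_sd=0.0,
        )
        omega = np.gradient(trial.joint_angles[:, 3], 1 / 60.0)
        assert abs(
            int(np.argmax(trial.gt_envelope[:, 3])) - int(np.argmax(np.abs(omega)))
        ) <= 1

    def test_trial_invariants(self, arm, catalog, gt_model):
        trial = synthesize_trial(arm, catalog[16], gt_model, seed=7)
        assert np.all(np.diff(trial.kin_timestamps) > 0)
        assert np.all(np.diff(trial.emg_timestamps) > 0)
        norms = np.linalg.norm(trial.eef_orientation, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        link1 = np.linalg.norm(trial.elbow - trial.shoulder, axis=1)
        link2 = np.linalg.norm(trial.wrist - trial.elbow, axis=1)
        np.testing.assert_allclose(link1, arm.upper_arm_length, atol=1e-9)
        np.testing.assert_allclose(link2, arm.forearm_length, atol=1e-9)

    def test_rms_recoverability_of_constant_envelope(self):
        # constant envelope a, no baseline noise: 200 ms RMS of a*eta ~ a
        rng = np.random.default_rng(0)
        a = 0.7
        t = np.arange(0, 4.0, 1 / 2222.0)
        raw = a * rng.standard_normal((len(t), 1))
        targets = np.arange(0.5, 3.5, 1 / 60.0)
        est = emg_preprocess.rms_resample(raw, t, targets)
        assert np.abs(est - a).mean() / a < 0.05


class TestStudyGeneration:
    def test_manifest_structure_defaults(self):
        manifest = build_manifest(StudyConfig(emulate_missing=True))
        assert len(manifest.tasks) == 23
        assert manifest.n_reps == 18
        assert len(common_tasks(manifest.availability)) == 15

    def test_generated_counts_and_reps(self, mini_manifest):
        assert len(mini_manifest.tasks) == 4
        for s in mini_manifest.subject_ids:
            for task in mini_manifest.available_tasks(s):
                assert len(mini_manifest.trials[(s, task)]) == 6

    def test_same_seed_bit_identical(self, catalog):
        cfg = StudyConfig(n_subjects=1, n_reps=2, tasks=catalog[:2])
        m1 = generate_study(cfg, seed=9)
        m2 = generate_study(cfg, seed=9)
        for key in m1.trials:
            for t1, t2 in zip(m1.trials[key], m2.trials[key]):
                assert np.array_equal(t1.raw_emg, t2.raw_emg)
                assert np.array_equal(t1.eef_position, t2.eef_position)
        assert m1.gt_hash == m2.gt_hash

    def test_calibrated_envelopes_in_unit_interval(self, mini_manifest):
        for trials in mini_manifest.trials.values():
            for t in trials:
                assert t.gt_envelope.min() >= 0.0
                assert t.gt_envelope.max() <= 1.0

    def test_round_trip_to_disk(self, catalog, tmp_path):
        cfg = StudyConfig(n_subjects=1, n_reps=1, tasks=catalog[:1])
        manifest = generate_study(cfg, seed=5, out_dir=tmp_path)
        assert (tmp_path / "manifest.json").exists()
        import json

        idx = json.loads((tmp_path / "manifest.json").read_text())
        stem = idx["trials"][f"1|{catalog[0].name}"][0]
        from kin2emg.synthetic_data import load_trial_csvs

        kin, emg = load_trial_csvs(tmp_path, stem)
        trial = manifest.trials[(1, catalog[0].name)][0]
        assert kin.shape == (len(trial.kin_timestamps), 17)
        assert emg.shape == (len(trial.emg_timestamps), 9)
        np.testing.assert_allclose(kin[:, 10:13], trial.eef_position, rtol=1e-6)
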