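"""Axis normalization, tilt compensation, rigid registration and
temporal-offset estimation."""

import dataclasses

import numpy as np
import pytest

from mocapval.alignment import (
    OffsetEstimate,
    RigidTransform,
    apply_transform,
    estimate_rigid_transform,
    normalize_axes,
    register_recordings,
    signed_permutation_matrix,
    temporal_offset_from_timestamps,
    tilt_compensation,
)
from mocapval.simulate import (
    SasTruth,
    SensorModel,
    SubjectTemplate,
    degrade,
    simulate_posture,
    simulate_sas,
)
from mocapval.skeleton import DataError, SkeletonRecording

from conftest import common_static_recording, random_recording


def random_rotation(rng, max_deg=180.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_deg, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


class TestRigidTransform:
    def test_identity(self):
        tf = RigidTransform.identity()
        p = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_array_equal(tf.apply_points(p), p)

    def test_apply_then_invert_restores(self, rng):
        for _ in range(20):
            tf = RigidTransform(random_rotation(rng), rng.normal(0, 100, 3), 0.1)
            p = rng.normal(0, 500, (30, 3))
            back = tf.inverse().apply_points(tf.apply_points(p))
            np.testing.assert_allclose(back, p, atol=1e-9)

    def test_improper_rotation_rejected(self):
        with pytest.raises(DataError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rigid_transform_preserves_distances(self, rng):
        tf = RigidTransform(random_rotation(rng), rng.normal(0, 300, 3))
        p = rng.normal(0, 500, (20, 3))
        q = tf.apply_points(p)
        d_p = np.linalg.norm(p[:, None] - p[None], axis=-1)
        d_q = np.linalg.norm(q[:, None] - q[None], axis=-1)
        np.testing.assert_allclose(d_p, d_q, atol=1e-9)


class TestAxisNormalization:
    def test_identity_permutation(self, rng):
        rec = random_recording(rng)
        out = normalize_axes(rec, ("x", "y", "z"))
        np.testing.assert_array_equal(out.positions, rec.positions)

    def test_swap_yz_with_negation(self):
        rec = SkeletonRecording(
            timestamps=np.array([0.0]),
            positions=np.array([[[1.0, 2.0, 3.0]]]),
            landmarks=("a",),
        )
        out = normalize_axes(rec, ("x", "-z", "y"))
        np.testing.assert_array_equal(out.positions[0, 0], [1.0, -3.0, 2.0])

    def test_non_permutation_rejected(self, rng):
        rec = random_recording(rng)
        with pytest.raises(DataError):
            normalize_axes(rec, np.array([[1, 1, 0], [0, 0, 1], [0, 0, 0]], float))

    def test_signed_permutations_compose_associatively(self, rng):
        axes = ["x", "y", "z"]
        for _ in range(100):
            mats = []
            for _ in range(3):
                perm = rng.permutation(3)
                signs = rng.choice(["", "-"], size=3)
                mats.append(
                    signed_permutation_matrix(
                        tuple(signs[i] + axes[perm[i]] for i in range(3))
                    )
                )
            A, B, C = mats
            np.testing.assert_array_equal((A @ B) @ C, A @ (B @ C))


class TestTiltCompensation:
    def test_level_normal_is_identity(self, static_common):
        out = tilt_compensation(static_common, np.array([0.0, 1.0, 0.0]))
        np.testing.assert_allclose(out.positions, static_common.positions)

    def test_pitched_scene_recovered(self):
        """A scene pitched by -9 deg is levelled by compensating with the
        equally pitched floor normal."""
        level = simulate_posture(
            truth=dataclasses.replace(
                simulate_posture().recording.meta["truth"], pitch_amp_deg=0.0, roll_amp_deg=0.0
            ),
            duration_s=2.0,
        ).recording
        theta = np.radians(-9.0)
        Rx = np.array(
            [
                [1, 0, 0],
                [0, np.cos(theta), -np.sin(theta)],
                [0, np.sin(theta), np.cos(theta)],
            ]
        )
        tilted = level.copy()
        tilted.positions = level.positions @ Rx.T
        normal = Rx @ np.array([0.0, 1.0, 0.0])
        out = tilt_compensation(tilted, normal)
        np.testing.assert_allclose(out.positions, level.positions, atol=1e-6)
        # vertical variance of the spine base is back to the level baseline
        v = out.get("spine_base")[:, 1]
        assert np.var(v) == pytest.approx(np.var(level.get("spine_base")[:, 1]), abs=1e-9)

    def test_idempotent_once_level(self, static_common):
        out1 = tilt_compensation(static_common, np.array([0.1, 0.99, 0.0]))
        out2 = tilt_compensation(out1, np.array([0.0, 1.0, 0.0]))
        np.testing.assert_allclose(out2.positions, out1.positions, atol=1e-9)

    def test_degenerate_normal_rejected(self, static_common):
        with pytest.raises(DataError):
            tilt_compensation(static_common, np.array([0.0, 0.0, 1.0]))
        with pytest.raises(DataError):
            tilt_compensation(static_common, np.zeros(3))


class TestKabsch:
    def test_identity_when_dst_equals_src(self, rng):
        src = rng.normal(0, 100, (10, 3))
        tf = estimate_rigid_transform(src, src)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)
        assert tf.residual_rms_mm < 1e-9

    def test_constructed_transform_recovered_exactly(self, rng):
        theta = np.radians(10.0)
        R = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        t = np.array([100.0, 0.0, -50.0])
        src = rng.normal(0, 300, (21, 3))
        dst = src @ R.T + t
        tf = estimate_rigid_transform(src, dst)
        np.testing.assert_allclose(tf.rotation, R, atol=1e-9)
        np.testing.assert_allclose(tf.translation, t, atol=1e-9)
        assert tf.residual_rms_mm < 1e-9

    def test_noisy_recovery_within_half_degree(self, rng):
        theta = np.radians(7.0)
        R = np.array(
            [
                [np.cos(theta), 0, np.sin(theta)],
                [0, 1, 0],
                [-np.sin(theta), 0, np.cos(theta)],
            ]
        )
        t = np.array([120.0, -40.0, 300.0])
        src = np.tile(rng.normal(0, 400, (21, 3)), (100, 1))
        dst = src @ R.T + t + rng.normal(0, 5.0, src.shape)
        tf = estimate_rigid_transform(src, dst)
        err = tf.compose(RigidTransform(R.T, -R.T @ t)).rotation_angle_deg()
        assert err < 0.5

    def test_matches_small_angle_grid_search_oracle(self, rng):
        """On a 4-point planar-yaw toy, the SVD solution matches an
        exhaustive grid search over yaw angle."""
        src = np.array(
            [[100.0, 0, 0], [-100.0, 0, 0], [0, 100.0, 50.0], [0, -100.0, -50.0]]
        )
        theta_true = np.radians(3.0)
        Ry = lambda a: np.array(
            [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
        )
        dst = src @ Ry(theta_true).T + np.array([5.0, -2.0, 3.0])
        dst += rng.normal(0, 1.0, dst.shape) * np.array([1, 0, 1])  # in-plane noise
        tf = estimate_rigid_transform(src, dst)
        # brute force: best pure-yaw rotation + optimal translation
        best = (np.inf, None)
        for a in np.arange(-0.2, 0.2, 1e-5):
            R = Ry(a)
            t = dst.mean(0) - R @ src.mean(0)
            resid = np.sqrt(np.mean(np.sum((dst - (src @ R.T + t)) ** 2, axis=1)))
            if resid < best[0]:
                best = (resid, a)
        rms_svd = np.sqrt(np.mean(np.sum((dst - tf.apply_points(src)) ** 2, axis=1)))
        assert rms_svd <= best[0] + 1e-3

    def test_collinear_configuration_rejected(self):
        src = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DataError):
            estimate_rigid_transform(src, src + 1.0)

    def test_estimate_inverts_apply_on_random_transforms(self, rng):
        for _ in range(100):
            tf = RigidTransform(random_rotation(rng, 10.0), rng.uniform(-500, 500, 3))
            src = rng.normal(0, 400, (15, 3))
            est = estimate_rigid_transform(src, tf.apply_points(src))
            np.testing.assert_allclose(est.rotation, tf.rotation, atol=1e-9)
            np.testing.assert_allclose(est.translation, tf.translation, atol=1e-6)


class TestApplyTransform:
    def test_pure_translation_adds_to_axis(self, static_common):
        tf = RigidTransform(np.eye(3), np.array([0.0, 0.0, 100.0]))
        out = apply_transform(static_common, tf)
        np.testing.assert_allclose(
            out.positions[..., 2], static_common.positions[..., 2] + 100.0
        )

    def test_apply_then_inverse_restores(self, rng, static_common):
        tf = RigidTransform(random_rotation(rng), rng.normal(0, 200, 3), 0.25)
        back = apply_transform(apply_transform(static_common, tf), tf.inverse())
        np.testing.assert_allclose(back.positions, static_common.positions, atol=1e-9)
        np.testing.assert_allclose(back.timestamps, static_common.timestamps, atol=1e-12)


class TestTemporalOffset:
    def test_zero_offset_without_refinement(self, static_common):
        est = temporal_offset_from_timestamps(static_common, static_common, 0.0)
        assert est.offset_s == 0.0 and not est.refined

    def test_clock_shift_recovered_on_transition_task(self):
        ref = simulate_sas(truth=SasTruth(n_cycles=2)).recording
        sensor = ref.copy()
        sensor.timestamps = ref.timestamps + 0.50
        sensor.nominal_rate = 30.0
        # declared offset deliberately off by 0.1 s; refinement recovers it
        est = temporal_offset_from_timestamps(ref, sensor, 0.40, refine=True)
        assert est.refined
        assert est.offset_s == pytest.approx(0.50, abs=1.0 / 30.0)

    def test_quiet_stance_falls_back_flagged(self):
        rec = simulate_posture(duration_s=10.0).recording
        sensor = rec.copy()
        sensor.timestamps = rec.timestamps + 0.3
        est = temporal_offset_from_timestamps(rec, sensor, 0.3, refine=True)
        assert est.fallback and est.offset_s == 0.3


class TestRegistration:
    def test_full_recovery_from_noiseless_degraded_recording(self):
        model = dataclasses.replace(
            SensorModel.none(),
            yaw_deg=7.0,
            translation_mm=(120.0, -40.0, 300.0),
            time_offset_s=0.4,
        )
        ref = simulate_sas(truth=SasTruth(n_cycles=2))
        sensor, truth = degrade(ref, model, seed=3)
        declared = float(sensor.recording.timestamps[0] - ref.recording.timestamps[0])
        assert declared == pytest.approx(0.4, abs=1e-9)
        tf = register_recordings(ref.recording, sensor.recording, time_offset_s=declared)
        np.testing.assert_allclose(tf.rotation, truth.rotation, atol=1e-9)
        np.testing.assert_allclose(tf.translation, truth.translation, atol=1e-6)
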