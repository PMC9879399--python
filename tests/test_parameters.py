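"""Event detection and clinical parameter extraction for the four tasks."""

import dataclasses
import math

import numpy as np
import pytest

from mocapval import parameters as P
from mocapval.simulate import (
    GaitTruth,
    PostureTruth,
    SasTruth,
    SipTruth,
    logistic_threshold_duration,
    simulate_gait,
    simulate_posture,
    simulate_sas,
    simulate_sip,
)
from mocapval.skeleton import DataError, Task

from conftest import common_static_recording


class TestSwayAngles:
    def test_vertical_static_skeleton_has_zero_sway(self, static_common):
        sway = P.sway_angles(static_common)
        np.testing.assert_allclose(sway.pitch_deg, 0.0, atol=1e-9)
        np.testing.assert_allclose(sway.roll_deg, 0.0, atol=1e-9)

    def test_pure_ap_displacement_gives_atan_pitch(self, static_common):
        rec = static_common.copy()
        base = rec.get("spine_base")
        anchor = 0.5 * (rec.get("ankle_l") + rec.get("ankle_r"))
        h = float(base[0, 1] - anchor[0, 1])
        d = 120.0
        rec.positions[:, rec.index("spine_base"), 2] += d
        sway = P.sway_angles(rec)
        np.testing.assert_allclose(
            sway.pitch_deg, math.degrees(math.atan(d / h)), rtol=1e-9
        )
        np.testing.assert_allclose(sway.roll_deg, 0.0, atol=1e-9)

    def test_simulated_sinusoidal_sway_recovered(self):
        truth = PostureTruth(pitch_amp_deg=0.5, roll_amp_deg=0.0, freq_hz=0.25)
        rec = simulate_posture(truth=truth, duration_s=20.0).recording
        sway = P.sway_angles(rec)
        expected = 0.5 * np.sin(2 * np.pi * 0.25 * rec.timestamps)
        assert np.abs(sway.pitch_deg - expected).max() < 0.01 * 0.5


class TestPostureParameters:
    def test_constant_series_all_zero(self):
        t = np.arange(100) / 30.0
        sway = P.SwaySeries(t, np.full(100, 2.0), np.full(100, -1.0))
        ps = P.posture_parameters(sway)
        assert all(v == 0.0 for v in ps.values.values())

    def test_sinusoid_range_and_mean_speed(self):
        # mean |d/dt A sin(2 pi f t)| = 4 A f
        t = np.arange(0, 40, 1 / 30)
        A, f = 0.5, 0.25
        sway = P.SwaySeries(t, A * np.sin(2 * np.pi * f * t), np.zeros(t.size))
        ps = P.posture_parameters(sway)
        assert ps["pitch_sway_range_deg"] == pytest.approx(2 * A, rel=0.02)
        assert ps["pitch_sway_speed_dps"] == pytest.approx(4 * A * f, rel=0.02)
        assert ps["roll_sway_range_deg"] == 0.0

    def test_roll_only_3d_range_equals_roll_range(self):
        t = np.arange(0, 40, 1 / 30)
        sway = P.SwaySeries(t, np.zeros(t.size), 0.3 * np.sin(2 * np.pi * 0.2 * t))
        ps = P.posture_parameters(sway)
        assert ps["pitch_sway_range_deg"] == 0.0
        assert ps["sway_range_3d_deg"] == pytest.approx(ps["roll_sway_range_deg"], rel=1e-6)

    def test_too_few_frames_rejected(self):
        with pytest.raises(DataError):
            P.posture_parameters(P.SwaySeries(np.array([0.0]), np.zeros(1), np.zeros(1)))


class TestTransitions:
    def test_flat_trajectory_yields_no_events(self, static_common):
        assert P.detect_transitions(static_common) == []

    def test_five_cycles_give_five_up_five_down_alternating(self):
        rec = simulate_sas(truth=SasTruth(n_cycles=5)).recording
        events = P.detect_transitions(rec)
        kinds = [e.kind for e in events]
        assert kinds.count(P.TransitionKind.STAND_UP) == 5
        assert kinds.count(P.TransitionKind.SIT_DOWN) == 5
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_logistic_duration_matches_analytic_threshold_crossing(self):
        rise = 1.20
        truth = SasTruth(rise_time_up_s=rise, rise_time_down_s=rise, n_cycles=3)
        rec = simulate_sas(truth=truth).recording
        events = P.detect_transitions(rec)
        # brute-force oracle on the closed-form logistic speed profile
        tau = rise / (2 * math.log(9.0))
        tt = np.linspace(-6 * tau, 6 * tau, 200001)
        speed = np.exp(tt / tau) / (1 + np.exp(tt / tau)) ** 2
        above = tt[speed >= 0.1 * speed.max()]
        analytic = above[-1] - above[0]
        assert analytic == pytest.approx(logistic_threshold_duration(rise), abs=1e-4)
        for e in events:
            assert e.duration_s == pytest.approx(analytic, abs=0.1)


class TestSasParameters:
    def test_mean_of_two_standup_durations(self, static_common):
        events = [
            P.TransitionEvent(P.TransitionKind.STAND_UP, 1.0, 2.2),
            P.TransitionEvent(P.TransitionKind.SIT_DOWN, 3.0, 4.0),
            P.TransitionEvent(P.TransitionKind.STAND_UP, 5.0, 6.6),
        ]
        rec = common_static_recording(n_frames=300)
        ps = P.sas_parameters(rec, events)
        assert ps["transition_time_up_s"] == pytest.approx(1.4)

    def test_motionless_hands_have_zero_range(self, static_common):
        events = [
            P.TransitionEvent(P.TransitionKind.STAND_UP, 0.2, 0.8),
            P.TransitionEvent(P.TransitionKind.SIT_DOWN, 1.0, 1.5),
        ]
        ps = P.sas_parameters(static_common, events)
        assert ps["hand_ap_range_up_m"] == 0.0
        assert ps["hand_ap_range_down_m"] == 0.0

    def test_constructed_ap_excursion_recovered(self):
        truth = SasTruth(ap_excursion_m=0.44, n_cycles=3)
        rec = simulate_sas(truth=truth).recording
        ps = P.sas_parameters(rec, P.detect_transitions(rec))
        assert ps["ap_deflection_range_up_m"] == pytest.approx(0.44, abs=0.01)

    def test_missing_kind_rejected(self, static_common):
        with pytest.raises(DataError):
            P.sas_parameters(
                static_common, [P.TransitionEvent(P.TransitionKind.STAND_UP, 0.1, 0.5)]
            )


class TestSipSteps:
    def test_static_knees_yield_no_steps(self, static_common):
        assert P.detect_sip_steps(static_common) == []

    def test_alternating_lifts_counted_per_knee(self):
        truth = SipTruth(period_s=1.25, lift_duration_s=0.8, first_lift_s=0.3)
        rec = simulate_sip(truth=truth, duration_s=40.0).recording
        events = P.detect_sip_steps(rec)
        n_l = sum(1 for e in events if e.side == "l")
        n_r = sum(1 for e in events if e.side == "r")
        exp = truth.expected_parameters(40.0)
        assert n_l + n_r == exp["step_count"]
        assert abs(n_l - n_r) <= 1

    def test_count_robust_to_5mm_noise(self, rng):
        truth = SipTruth(period_s=1.25, lift_duration_s=0.8)
        rec = simulate_sip(truth=truth, duration_s=40.0).recording
        n0 = len(P.detect_sip_steps(rec))
        noisy = rec.copy()
        noisy.positions = rec.positions + rng.normal(0, 5.0, rec.positions.shape)
        assert len(P.detect_sip_steps(noisy)) == n0

    def test_zero_lift_flagged_as_no_steps(self, static_common):
        events = P.detect_sip_steps(static_common)
        assert events == []


class TestSipParameters:
    def test_cadence_and_step_time_arithmetic(self):
        # 64 events in 40 s -> 96 steps/min, mean interval 0.625 s
        events = []
        for i in range(64):
            side = "l" if i % 2 == 0 else "r"
            tpeak = 0.3 + 0.625 * i
            events.append(
                P.StepEvent(side, tpeak, lift_time_s=tpeak - 0.2, land_time_s=tpeak + 0.2)
            )
        rec = common_static_recording(n_frames=1200)
        ps = P.sip_parameters(rec, events, duration_s=40.0)
        assert ps["cadence_steps_per_min"] == pytest.approx(96.0)
        assert ps["step_time_s"] == pytest.approx(0.625)

    def test_symmetric_stepping_has_equal_stance_times(self):
        rec = simulate_sip(duration_s=40.0).recording
        events = P.detect_sip_steps(rec)
        stance = {}
        for side in ("l", "r"):
            evs = [e for e in events if e.side == side]
            stance[side] = np.mean(
                [n.lift_time_s - p.land_time_s for p, n in zip(evs, evs[1:])]
            )
        assert stance["l"] == pytest.approx(stance["r"], rel=0.02)

    def test_knee_prominence_reported_in_cm(self):
        truth = SipTruth(lift_m=0.24)
        rec = simulate_sip(truth=truth).recording
        ps = P.sip_parameters(rec, P.detect_sip_steps(rec), 40.0)
        assert ps["knee_amplitude_cm"] == pytest.approx(24.0, rel=0.02)

    def test_cadence_step_time_consistency(self):
        """cadence x mean step time ~ 60; exact only up to the boundary
        effect of the first/last step not spanning the full recording
        (one stepping period over the task duration)."""
        rec = simulate_sip().recording
        truth = rec.meta["truth"]
        ps = P.sip_parameters(rec, P.detect_sip_steps(rec), rec.duration)
        tol = truth.period_s / rec.duration + 0.005
        assert ps["cadence_steps_per_min"] * ps["step_time_s"] == pytest.approx(
            60.0, rel=tol
        )


class TestGaitEvents:
    def test_stationary_skeleton_yields_no_contacts(self, static_common):
        assert P.detect_gait_events(static_common) == []

    def test_simulated_gait_contacts_alternate(self):
        truth = GaitTruth(speed_mps=1.2, step_period_s=0.5, path_m=3.6)
        rec = simulate_gait(truth=truth).recording
        events = P.detect_gait_events(rec)
        assert len(events) == truth.expected_parameters()["scsw_step_count"]
        sides = [e.side for e in events]
        assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_contacts_stable_under_5mm_noise(self, rng):
        rec = simulate_gait().recording
        base = P.detect_gait_events(rec)
        noisy = rec.copy()
        noisy.positions = rec.positions + rng.normal(0, 5.0, rec.positions.shape)
        pert = P.detect_gait_events(noisy)
        assert len(pert) == len(base)
        # stable to within one sensor-rate frame
        for a, b in zip(base, pert):
            assert abs(a.peak_time_s - b.peak_time_s) <= 1.0 / 30.0 + 1e-9


class TestGaitParameters:
    def test_constant_speed_recovered(self):
        truth = GaitTruth(speed_mps=1.11)
        rec = simulate_gait(truth=truth).recording
        ps = P.gait_parameters(rec, P.detect_gait_events(rec))
        assert ps["gait_speed_mps"] == pytest.approx(1.11, rel=0.01)

    def test_contact_arithmetic(self):
        """Contacts every 0.51 s at 1.27 m/s give 117.6 steps/min and
        64.8 cm steps."""
        truth = GaitTruth(speed_mps=1.27, step_period_s=0.51, path_m=4.0)
        rec = simulate_gait(truth=truth).recording
        ps = P.gait_parameters(rec, P.detect_gait_events(rec))
        assert ps["step_duration_s"] == pytest.approx(0.51, rel=0.02)
        assert ps["cadence_steps_per_min"] == pytest.approx(117.6, rel=0.02)
        assert ps["step_length_cm"] == pytest.approx(64.8, rel=0.02)

    def test_symmetric_arms_have_zero_symmetry_angle(self):
        truth = GaitTruth(arm_amp_l_deg=25.0, arm_amp_r_deg=25.0)
        rec = simulate_gait(truth=truth).recording
        ps = P.gait_parameters(rec, P.detect_gait_events(rec))
        assert ps["arm_amplitude_deg"] == pytest.approx(25.0, rel=0.02)
        assert ps["arm_symmetry_angle"] == pytest.approx(0.0, abs=0.01)

    def test_short_path_returns_speed_but_not_cycle_parameters(self):
        truth = GaitTruth(speed_mps=1.2, step_period_s=0.5, path_m=0.8)
        rec = simulate_gait(truth=truth).recording
        events = P.detect_gait_events(rec)
        ps = P.gait_parameters(rec, [] if len(events) < 2 else events[:1])
        assert np.isfinite(ps["gait_speed_mps"])
        assert math.isnan(ps["step_length_cm"])
        assert ps.flags


class TestSymmetryAngle:
    def test_equal_amplitudes_zero(self):
        assert P.symmetry_angle(20.0, 20.0) == 0.0

    def test_double_amplitude_closed_form(self):
        # |45 - atan(2) in deg| / 90 = 0.204833...
        expected = abs(45.0 - math.degrees(math.atan(2.0))) / 90.0
        assert P.symmetry_angle(30.0, 15.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2048, abs=3e-4)

    def test_symmetric_in_arguments(self, rng):
        for _ in range(50):
            a, b = rng.uniform(1.0, 60.0, 2)
            assert P.symmetry_angle(a, b) == pytest.approx(P.symmetry_angle(b, a), abs=1e-12)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(DataError):
            P.symmetry_angle(0.0, 10.0)


class TestSchema:
    def test_all_23_canonical_parameters_produced(self):
        """The four tasks together yield exactly the 23 canonical
        parameters (plus the auxiliary walk step count)."""
        schema_names = [n for names in P.PARAMETER_SCHEMA.values() for n in names]
        assert len(schema_names) == 23
        produced = {}
        for task, sim in (
            (Task.POCO, simulate_posture),
            (Task.SAS, simulate_sas),
            (Task.SIP, simulate_sip),
            (Task.SCSW, simulate_gait),
        ):
            ps = P.extract_parameters(sim().recording, task)
            produced[task] = set(ps.values)
        for task, names in P.PARAMETER_SCHEMA.items():
            assert set(names) <= produced[task]
        assert produced[Task.SCSW] - set(P.PARAMETER_SCHEMA[Task.SCSW]) == {
            "scsw_step_count"
        }
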