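"""Synthetic paired recordings for the four motor tasks.

The simulators stand in for raw study recordings: a high-rate (178 Hz)
reference recording is generated from analytically simple motion
primitives (sinusoidal sway, logistic sit-to-stand profiles, raised-cosine
steps, constant-speed gait with sinusoidal limb oscillation), so every
clinical parameter has a closed-form injected ground truth.  A
:class:`SensorModel` then degrades the reference into a markerless-sensor
recording: rigid misalignment, clock offset, ~30 Hz resampling with
jitter, per-body-region Gaussian noise, systematic offset and short
dropouts — exactly the defects the preprocessing and alignment stages must
undo.

Realism is deliberately secondary to testability: the primitives are not
biomechanically validated joint kinematics, they are signals whose derived
parameters are known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .alignment import RigidTransform
from .preprocess import sample_at
from .skeleton import (
    AXIS_AP,
    AXIS_ML,
    AXIS_V,
    COMMON_LANDMARKS,
    DataError,
    LANDMARK_CLASS,
    SkeletonRecording,
    System,
    Task,
    TaskRecording,
)

__all__ = [
    "SubjectTemplate",
    "PostureTruth",
    "SasTruth",
    "SipTruth",
    "GaitTruth",
    "SensorModel",
    "simulate_posture",
    "simulate_sas",
    "simulate_sip",
    "simulate_gait",
    "simulate_task",
    "degrade",
    "sample_subject_truths",
    "logistic_threshold_duration",
]

REFERENCE_RATE_HZ = 178.0
SENSOR_RATE_HZ = 30.0
STANDING_DISTANCE_MM = 2500.0
WALK_END_DISTANCE_MM = 1500.0


# ---------------------------------------------------------------------------
# static skeleton template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectTemplate:
    """Static 21-landmark standing pose parameterised by stature.

    Segment heights follow standard anthropometric fractions of stature;
    the pose faces the sensor (forward = decreasing AP) and the spine base
    stands vertically above the ankle midpoint so the quiet-stance sway
    vector is vertical at rest.
    """

    stature_mm: float = 1765.0
    standing_ap_mm: float = STANDING_DISTANCE_MM

    def pose(self) -> dict[str, np.ndarray]:
        h = self.stature_mm
        z0 = self.standing_ap_mm
        sh_half = 0.10 * h  # shoulder half width
        hip_half = 0.05 * h
        ank_half = 0.04 * h
        arm_x = sh_half + 0.01 * h

        def p(x: float, y: float, z: float = z0) -> np.ndarray:
            return np.array([x, y, z], dtype=float)

        pose = {
            "head": p(0.0, 0.94 * h),
            "neck": p(0.0, 0.87 * h),
            "spine_shoulder": p(0.0, 0.818 * h),
            "shoulder_l": p(-sh_half, 0.818 * h),
            "shoulder_r": p(sh_half, 0.818 * h),
            "elbow_l": p(-arm_x, 0.63 * h),
            "elbow_r": p(arm_x, 0.63 * h),
            "wrist_l": p(-arm_x, 0.485 * h),
            "wrist_r": p(arm_x, 0.485 * h),
            "hand_l": p(-arm_x, 0.44 * h),
            "hand_r": p(arm_x, 0.44 * h),
            "spine_mid": p(0.0, 0.67 * h),
            "spine_base": p(0.0, 0.53 * h),
            "hip_l": p(-hip_half, 0.52 * h),
            "hip_r": p(hip_half, 0.52 * h),
            "knee_l": p(-ank_half, 0.285 * h),
            "knee_r": p(ank_half, 0.285 * h),
            "ankle_l": p(-ank_half, 0.039 * h),
            "ankle_r": p(ank_half, 0.039 * h),
            "foot_l": p(-ank_half, 0.02 * h, z0 - 0.08 * h),
            "foot_r": p(ank_half, 0.02 * h, z0 - 0.08 * h),
        }
        # anatomical vertical ordering sanity check
        for lo, hi in (
            ("ankle_l", "knee_l"),
            ("knee_l", "hip_l"),
            ("hip_l", "shoulder_l"),
            ("shoulder_l", "head"),
        ):
            if not pose[lo][AXIS_V] < pose[hi][AXIS_V]:
                raise DataError("template violates vertical landmark ordering")
        return pose

    def pose_array(self) -> np.ndarray:
        pose = self.pose()
        return np.stack([pose[lm] for lm in COMMON_LANDMARKS])


def _make_recording(
    t: np.ndarray, pos: np.ndarray, rate: float, meta: dict | None = None
) -> SkeletonRecording:
    return SkeletonRecording(
        timestamps=t,
        positions=pos,
        landmarks=COMMON_LANDMARKS,
        nominal_rate=rate,
        frame_label="reference",
        meta=meta or {},
    )


def _wrap(
    rec: SkeletonRecording, task: Task, subject_id: str, repetition: int
) -> TaskRecording:
    return TaskRecording(
        task=task,
        subject_id=subject_id,
        repetition_index=repetition,
        system=System.REFERENCE,
        recording=rec,
    )


_IDX = {lm: i for i, lm in enumerate(COMMON_LANDMARKS)}
_UPPER_BODY = (
    "head",
    "neck",
    "spine_shoulder",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
    "hand_l",
    "hand_r",
    "spine_mid",
    "spine_base",
    "hip_l",
    "hip_r",
)
_LEAN_LANDMARKS = ("head", "neck", "spine_shoulder", "shoulder_l", "shoulder_r")
_HAND_CHAIN = ("wrist_l", "wrist_r", "hand_l", "hand_r")


# ---------------------------------------------------------------------------
# POCO — quiet stance with sinusoidal angular sway
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PostureTruth:
    """Injected sway: pitch and roll sinusoids about the ankle pivot."""

    pitch_amp_deg: float = 0.5
    roll_amp_deg: float = 0.3
    freq_hz: float = 0.25
    roll_phase_rad: float = 0.0  # in-phase with pitch by default

    def expected_parameters(self) -> dict[str, float]:
        a_p, a_r, f = self.pitch_amp_deg, self.roll_amp_deg, self.freq_hz
        if self.roll_phase_rad != 0.0:
            raise NotImplementedError(
                "closed forms implemented for in-phase sway only"
            )
        a3 = math.hypot(a_p, a_r)
        return {
            "pitch_sway_range_deg": 2 * a_p,
            "roll_sway_range_deg": 2 * a_r,
            # in-phase sway traces a line segment of half-length a3
            # through the upright orientation
            "sway_range_3d_deg": 2 * a3,
            "pitch_sway_speed_dps": 4 * a_p * f,  # mean|cos| = 2/pi
            "roll_sway_speed_dps": 4 * a_r * f,
            "sway_speed_3d_dps": 4 * a3 * f,
        }


def simulate_posture(
    template: SubjectTemplate = SubjectTemplate(),
    truth: PostureTruth = PostureTruth(),
    duration_s: float = 40.0,
    rate: float = REFERENCE_RATE_HZ,
    seed: int = 0,
    subject_id: str = "sim",
    repetition: int = 1,
) -> TaskRecording:
    """Whole-skeleton rigid sway about the ankle midpoint; feet fixed."""
    if abs(truth.pitch_amp_deg) >= 90 or abs(truth.roll_amp_deg) >= 90:
        raise DataError("sway amplitude must stay below 90 deg")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    pose = template.pose_array()
    pivot = 0.5 * (pose[_IDX["ankle_l"]] + pose[_IDX["ankle_r"]])
    w = 2 * math.pi * truth.freq_hz
    pitch = np.radians(truth.pitch_amp_deg) * np.sin(w * t)
    roll = np.radians(truth.roll_amp_deg) * np.sin(w * t + truth.roll_phase_rad)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    zero = np.zeros_like(t)
    one = np.ones_like(t)
    # pitch about ML (x), then roll about AP (z) with the sign that makes
    # the extracted frontal inclination equal the injected roll
    rx = np.stack(
        [
            np.stack([one, zero, zero], -1),
            np.stack([zero, cp, -sp], -1),
            np.stack([zero, sp, cp], -1),
        ],
        1,
    )
    rz = np.stack(
        [
            np.stack([cr, sr, zero], -1),
            np.stack([-sr, cr, zero], -1),
            np.stack([zero, zero, one], -1),
        ],
        1,
    )
    R = np.einsum("nij,njk->nik", rz, rx)
    rel = pose - pivot
    pos = np.einsum("nij,lj->nli", R, rel) + pivot
    for lm in ("ankle_l", "ankle_r", "foot_l", "foot_r"):
        pos[:, _IDX[lm], :] = pose[_IDX[lm]]
    rec = _make_recording(t, pos, rate, {"truth": truth})
    return _wrap(rec, Task.POCO, subject_id, repetition)


# ---------------------------------------------------------------------------
# SAS — stand up and sit down with logistic vertical profiles
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def logistic_threshold_duration(rise_10_90_s: float, fraction: float = 0.1) -> float:
    """Duration between the two crossings of ``fraction`` of the peak
    vertical speed, for a logistic height profile with the given 10-90%
    rise time (closed form)."""
    tau = rise_10_90_s / (2.0 * math.log(9.0))
    # speed ∝ s(1-s); fraction of the peak 1/4 gives s(1-s) = fraction/4
    s_hi = (1.0 + math.sqrt(1.0 - fraction)) / 2.0
    s_lo = 1.0 - s_hi
    logit = lambda s: math.log(s / (1.0 - s))
    return tau * (logit(s_hi) - logit(s_lo))


@dataclass(frozen=True)
class SasTruth:
    """Injected sit-to-stand cycle shape."""

    rise_time_up_s: float = 0.89  # 10-90% rise of the vertical profile
    rise_time_down_s: float = 0.95
    height_gain_m: float = 0.30
    ap_excursion_m: float = 0.43
    hand_ap_range_m: float = 0.39
    n_cycles: int = 5
    pre_pause_s: float = 2.0
    hold_s: float = 2.5

    def expected_parameters(self) -> dict[str, float]:
        return {
            "transition_time_up_s": logistic_threshold_duration(self.rise_time_up_s),
            "transition_time_down_s": logistic_threshold_duration(
                self.rise_time_down_s
            ),
            "ap_deflection_range_up_m": self.ap_excursion_m,
            "ap_deflection_range_down_m": self.ap_excursion_m,
            "hand_ap_range_up_m": self.hand_ap_range_m,
            "hand_ap_range_down_m": self.hand_ap_range_m,
        }

    def schedule(self) -> tuple[list[float], list[float], float]:
        """Transition centre times (stand-ups, sit-downs) and total duration."""
        d_up = logistic_threshold_duration(self.rise_time_up_s)
        d_down = logistic_threshold_duration(self.rise_time_down_s)
        cycle = self.pre_pause_s + d_up + self.hold_s + d_down
        ups, downs = [], []
        for i in range(self.n_cycles):
            c_up = i * cycle + self.pre_pause_s + d_up / 2.0
            ups.append(c_up)
            downs.append(c_up + d_up / 2.0 + self.hold_s + d_down / 2.0)
        total = self.n_cycles * cycle + self.pre_pause_s
        return ups, downs, total


def simulate_sas(
    template: SubjectTemplate = SubjectTemplate(),
    truth: SasTruth = SasTruth(),
    rate: float = REFERENCE_RATE_HZ,
    seed: int = 0,
    subject_id: str = "sim",
    repetition: int = 1,
) -> TaskRecording:
    """Repeated chair transitions: logistic vertical trunk profiles with
    Gaussian AP lean/reach bumps phase-locked to each transition."""
    if truth.rise_time_up_s <= 0 or truth.rise_time_down_s <= 0:
        raise DataError("rise times must be positive")
    ups, downs, total = truth.schedule()
    n = int(round(total * rate))
    t = np.arange(n) / rate
    tau_up = truth.rise_time_up_s / (2 * math.log(9.0))
    tau_down = truth.rise_time_down_s / (2 * math.log(9.0))
    height = np.zeros_like(t)
    lean = np.zeros_like(t)
    for c_up, c_down in zip(ups, downs):
        height += _logistic((t - c_up) / tau_up)
        height -= _logistic((t - c_down) / tau_down)
        # forward-lean bump, fully contained in the transition window
        lean += np.exp(-((t - c_up) ** 2) / (2 * tau_up**2))
        lean += np.exp(-((t - c_down) ** 2) / (2 * tau_down**2))
    height_mm = truth.height_gain_m * 1000.0 * height
    lean_mm = truth.ap_excursion_m * 1000.0 * lean
    reach_mm = truth.hand_ap_range_m * 1000.0 * lean
    pose = template.pose_array()
    pos = np.broadcast_to(pose, (n, *pose.shape)).copy()
    for lm in _UPPER_BODY:
        pos[:, _IDX[lm], AXIS_V] += height_mm
    for lm in _LEAN_LANDMARKS:
        pos[:, _IDX[lm], AXIS_AP] -= lean_mm  # forward = toward the sensor
    for lm in ("spine_mid", "spine_base", "hip_l", "hip_r"):
        # the pelvis shifts forward over the feet during a transition
        pos[:, _IDX[lm], AXIS_AP] -= 0.35 * lean_mm
    for lm in _HAND_CHAIN:
        pos[:, _IDX[lm], AXIS_AP] -= reach_mm
    for lm in ("elbow_l", "elbow_r"):
        pos[:, _IDX[lm], AXIS_AP] -= 0.5 * reach_mm
    rec = _make_recording(t, pos, rate, {"truth": truth})
    return _wrap(rec, Task.SAS, subject_id, repetition)


# ---------------------------------------------------------------------------
# SIP — stepping in place with raised-cosine knee lifts
# ---------------------------------------------------------------------------

def _raised_cosine(t: np.ndarray, starts: np.ndarray, width: float) -> np.ndarray:
    """Sum of unit raised-cosine bumps with given start times and width."""
    out = np.zeros_like(t)
    for s in starts:
        mask = (t >= s) & (t <= s + width)
        out[mask] += 0.5 * (1.0 - np.cos(2 * math.pi * (t[mask] - s) / width))
    return out


@dataclass(frozen=True)
class SipTruth:
    """Injected on-the-spot stepping: anti-phase raised-cosine lifts."""

    period_s: float = 1.36  # per knee (two steps per period overall)
    lift_m: float = 0.24  # planar (AP-V) displacement prominence
    lift_duration_s: float = 0.88  # ~65% duty: knee rests at baseline between lifts
    first_lift_s: float = 0.3
    ap_fraction: float = 0.6  # AP share of the planar lift vector

    def __post_init__(self) -> None:
        if self.lift_duration_s >= self.period_s:
            raise DataError("lift duration must be shorter than the period")

    def _lift_starts(self, duration_s: float, side: str) -> np.ndarray:
        t0 = self.first_lift_s + (0.0 if side == "l" else self.period_s / 2.0)
        starts = np.arange(t0, duration_s - self.lift_duration_s, self.period_s)
        return starts

    def expected_parameters(self, duration_s: float = 40.0) -> dict[str, float]:
        n_l = self._lift_starts(duration_s, "l").size
        n_r = self._lift_starts(duration_s, "r").size
        count = n_l + n_r
        w, p = self.lift_duration_s, self.period_s
        # 20%-of-peak crossing of a raised cosine: cos = 0.6
        t_cross = w * math.acos(0.6) / (2 * math.pi)
        return {
            "knee_amplitude_cm": self.lift_m * 100.0,
            "step_count": float(count),
            "cadence_steps_per_min": count / duration_s * 60.0,
            "step_time_s": p / 2.0,
            "stance_time_s": p - w + 2 * t_cross,
        }


def simulate_sip(
    template: SubjectTemplate = SubjectTemplate(),
    truth: SipTruth = SipTruth(),
    duration_s: float = 40.0,
    rate: float = REFERENCE_RATE_HZ,
    seed: int = 0,
    subject_id: str = "sim",
    repetition: int = 1,
) -> TaskRecording:
    """Stepping in place: knees (and the leg chain below) lift along a
    raised-cosine planar trajectory, trunk quasi-static."""
    if truth.period_s <= 2.0 / rate:
        raise DataError("stepping period too short for the sampling rate")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    pose = template.pose_array()
    pos = np.broadcast_to(pose, (n, *pose.shape)).copy()
    lift_mm = truth.lift_m * 1000.0
    ap_amp = truth.ap_fraction * lift_mm
    v_amp = math.sqrt(1.0 - truth.ap_fraction**2) * lift_mm
    for side in ("l", "r"):
        starts = truth._lift_starts(duration_s, side)
        bump = _raised_cosine(t, starts, truth.lift_duration_s)
        for lm, scale in ((f"knee_{side}", 1.0), (f"ankle_{side}", 0.9), (f"foot_{side}", 0.9)):
            pos[:, _IDX[lm], AXIS_V] += scale * v_amp * bump
            pos[:, _IDX[lm], AXIS_AP] -= scale * ap_amp * bump
    rec = _make_recording(t, pos, rate, {"truth": truth})
    return _wrap(rec, Task.SIP, subject_id, repetition)


# ---------------------------------------------------------------------------
# SCSW — walk toward the sensor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitTruth:
    """Injected gait: constant progression speed, sinusoidal limb motion."""

    speed_mps: float = 1.11
    step_period_s: float = 0.51
    arm_amp_l_deg: float = 33.6
    arm_amp_r_deg: float = 16.9
    path_m: float = 4.0

    def __post_init__(self) -> None:
        if self.path_m > 4.0 + 1e-9:
            raise DataError("walk path limited to 4 m of usable range")

    @property
    def stride_period_s(self) -> float:
        return 2.0 * self.step_period_s

    @property
    def duration_s(self) -> float:
        return self.path_m / self.speed_mps

    def contact_times(self, rate: float = SENSOR_RATE_HZ) -> list[tuple[str, float]]:
        """Analytic foot-contact times (peak ankle-ahead excursion) inside
        the usable walk, excluding the boundary samples."""
        T = self.stride_period_s
        end = self.duration_s
        margin = 1.0 / rate
        out: list[tuple[str, float]] = []
        for side, phase in (("l", 0.25), ("r", 0.75)):
            k = 0
            while True:
                tc = (phase + k) * T
                if tc > end - margin:
                    break
                if tc >= margin:
                    out.append((side, tc))
                k += 1
        return sorted(out, key=lambda x: x[1])

    def expected_parameters(self, rate: float = SENSOR_RATE_HZ) -> dict[str, float]:
        contacts = self.contact_times(rate)
        amp = (self.arm_amp_l_deg + self.arm_amp_r_deg) / 2.0
        gamma = abs(
            45.0 - math.degrees(math.atan(self.arm_amp_l_deg / self.arm_amp_r_deg))
        ) / 90.0
        out = {
            "gait_speed_mps": self.speed_mps,
            "scsw_step_count": float(len(contacts)),
            "step_duration_s": self.step_period_s,
            "cadence_steps_per_min": 60.0 / self.step_period_s,
            "step_length_cm": self.speed_mps * self.step_period_s * 100.0,
            "arm_amplitude_deg": amp,
            "arm_symmetry_angle": gamma,
        }
        return out


def simulate_gait(
    template: SubjectTemplate = SubjectTemplate(),
    truth: GaitTruth = GaitTruth(),
    rate: float = REFERENCE_RATE_HZ,
    seed: int = 0,
    subject_id: str = "sim",
    repetition: int = 1,
) -> TaskRecording:
    """Walk toward the sensor across the usable tracking range.

    The spine base advances at constant AP speed; ankles oscillate about
    it so the ankle-ahead excursion peaks once per stride per side; arms
    counter-swing sinusoidally with per-side amplitudes.
    """
    end = truth.duration_s
    n = int(round(end * rate))
    if n < 4:
        raise DataError("walk path too short to record")
    t = np.arange(n) / rate
    pose = template.pose_array()
    pos = np.broadcast_to(pose, (n, *pose.shape)).copy()
    # whole-body progression: start so the walk ends at the near range limit
    z_start = WALK_END_DISTANCE_MM + truth.path_m * 1000.0
    dz = z_start - template.standing_ap_mm - truth.speed_mps * 1000.0 * t
    pos[:, :, AXIS_AP] += dz[:, None]
    T = truth.stride_period_s
    step_amp_mm = truth.speed_mps * truth.step_period_s * 1000.0 / 2.0
    for side, phase in (("l", 0.0), ("r", math.pi)):
        osc = np.sin(2 * math.pi * t / T + phase)
        # contact (max ankle-ahead) happens when osc = 1 toward the sensor
        for lm, scale in ((f"ankle_{side}", 1.0), (f"foot_{side}", 1.0), (f"knee_{side}", 0.5)):
            pos[:, _IDX[lm], AXIS_AP] -= scale * step_amp_mm * osc
    # arms: sagittal inclination of the spine-shoulder -> wrist vector
    arm_len = {
        s: float(
            np.linalg.norm(pose[_IDX[f"wrist_{s}"]] - pose[_IDX[f"spine_shoulder"]])
        )
        for s in ("l", "r")
    }
    amps = {"l": truth.arm_amp_l_deg, "r": truth.arm_amp_r_deg}
    for side, phase in (("l", math.pi), ("r", 0.0)):
        theta = np.radians(amps[side]) * np.sin(2 * math.pi * t / T + phase)
        ss = pos[:, _IDX["spine_shoulder"], :]
        x_w = pose[_IDX[f"wrist_{side}"], AXIS_ML]
        wrist = np.empty((n, 3))
        wrist[:, AXIS_ML] = x_w
        wrist[:, AXIS_V] = ss[:, AXIS_V] - arm_len[side] * np.cos(theta)
        wrist[:, AXIS_AP] = ss[:, AXIS_AP] - arm_len[side] * np.sin(theta)
        pos[:, _IDX[f"wrist_{side}"], :] = wrist
        hand = wrist.copy()
        hand[:, AXIS_V] -= 40.0
        pos[:, _IDX[f"hand_{side}"], :] = hand
        elbow = 0.5 * (ss + wrist)
        elbow[:, AXIS_ML] = x_w
        pos[:, _IDX[f"elbow_{side}"], :] = elbow
    rec = _make_recording(t, pos, rate, {"truth": truth})
    return _wrap(rec, Task.SCSW, subject_id, repetition)


def simulate_task(
    task: Task,
    template: SubjectTemplate = SubjectTemplate(),
    truth=None,
    seed: int = 0,
    subject_id: str = "sim",
    repetition: int = 1,
    rate: float = REFERENCE_RATE_HZ,
) -> TaskRecording:
    """Dispatch to the task-specific simulator with its default truth."""
    task = Task(task)
    kw = dict(seed=seed, subject_id=subject_id, repetition=repetition, rate=rate)
    if task is Task.POCO:
        return simulate_posture(template, truth or PostureTruth(), **kw)
    if task is Task.SAS:
        return simulate_sas(template, truth or SasTruth(), **kw)
    if task is Task.SIP:
        return simulate_sip(template, truth or SipTruth(), **kw)
    if task is Task.SCSW:
        return simulate_gait(template, truth or GaitTruth(), **kw)
    raise ValueError(task)


# ---------------------------------------------------------------------------
# sensor degradation model
# ---------------------------------------------------------------------------

DEFAULT_NOISE_SD_MM: dict[str, float] = {
    "trunk": 20.0,
    "arms": 35.0,
    "knees": 55.0,
    "feet": 80.0,
}

#: qualitative per-axis anisotropy: depth-sensor noise is worst vertically
#: and smallest along the line of sight once aligned
DEFAULT_AXIS_MULTIPLIERS: tuple[float, float, float] = (1.0, 1.3, 0.7)


def _euler_rotation(yaw_deg: float, pitch_deg: float, roll_deg: float) -> np.ndarray:
    cy, sy = math.cos(math.radians(yaw_deg)), math.sin(math.radians(yaw_deg))
    cp, sp = math.cos(math.radians(pitch_deg)), math.sin(math.radians(pitch_deg))
    cr, sr = math.cos(math.radians(roll_deg)), math.sin(math.radians(roll_deg))
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])  # yaw about V
    Rx = np.array([[1, 0, 0], [0, cp, -sp], [0, sp, cp]])  # pitch about ML
    Rz = np.array([[cr, -sr, 0], [sr, cr, 0], [0, 0, 1]])  # roll about AP
    return Ry @ Rx @ Rz


@dataclass(frozen=True)
class SensorModel:
    """Degradation model turning a reference recording into a sensor one.

    ``noise_scale`` multiplies every per-class noise SD, which makes noise
    sweeps share their underlying random draws for a fixed seed (the unit
    noise is generated independently of the SDs and then scaled).
    """

    noise_sd_mm: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD_MM)
    )
    noise_scale: float = 1.0
    axis_multipliers: tuple[float, float, float] = DEFAULT_AXIS_MULTIPLIERS
    systematic_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    time_offset_s: float = 0.0
    rate_hz: float = SENSOR_RATE_HZ
    noise_corr_time_s: float = 0.2  # AR(1) correlation time; 0 = white noise
    jitter_sd_s: float = 0.0
    dropout_per_min: float = 0.0  # expected dropout gaps per landmark per minute
    dropout_max_ms: float = 200.0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_sd_mm.values()) or self.noise_scale < 0:
            raise DataError("noise SDs must be non-negative")

    def rotation_matrix(self) -> np.ndarray:
        return _euler_rotation(self.yaw_deg, self.pitch_deg, self.roll_deg)

    def scaled(self, factor: float) -> "SensorModel":
        return replace(self, noise_scale=self.noise_scale * factor)

    @classmethod
    def none(cls) -> "SensorModel":
        return cls(noise_sd_mm={k: 0.0 for k in DEFAULT_NOISE_SD_MM})

    @classmethod
    def default(cls) -> "SensorModel":
        return cls(
            yaw_deg=6.0,
            translation_mm=(150.0, -30.0, 250.0),
            time_offset_s=0.35,
            jitter_sd_s=0.002,
            dropout_per_min=2.0,
        )


def degrade(
    reference: TaskRecording, model: SensorModel, seed: int = 0
) -> tuple[TaskRecording, RigidTransform]:
    """Degrade a reference recording into a simulated sensor recording.

    Applies, in order: rigid misalignment, clock offset, resampling to the
    sensor rate with timestamp jitter, per-landmark-class Gaussian noise,
    systematic offset, and dropout gaps.  Returns the sensor recording and
    the true sensor-to-reference transform (the one the alignment stage
    must recover).  All randomness derives from ``seed``; random draws are
    independent of the noise SDs so noise sweeps reuse the same draws.
    """
    rng = np.random.default_rng(seed)
    rec = reference.recording
    R = model.rotation_matrix()
    t_vec = np.asarray(model.translation_mm, dtype=float)
    misaligned = rec.copy()
    misaligned.positions = rec.positions @ R.T + t_vec
    misaligned.timestamps = rec.timestamps + model.time_offset_s

    step = 1.0 / model.rate_hz
    n_out = int(math.floor(misaligned.duration / step)) + 1
    grid = misaligned.timestamps[0] + step * np.arange(n_out)
    jitter = rng.normal(0.0, 1.0, size=n_out) * model.jitter_sd_s
    times = grid + jitter
    times[0] = grid[0]  # anchor the declared clock offset at the first frame
    times = np.clip(times, misaligned.timestamps[0], misaligned.timestamps[-1])
    # drop frames knocked out of order by extreme jitter
    keep = np.concatenate([[True], np.diff(times) > 0])
    times = times[keep]
    sensor = sample_at(misaligned, times)
    sensor.nominal_rate = model.rate_hz
    sensor.frame_label = "sensor"

    n, n_lm = sensor.n_frames, len(sensor.landmarks)
    unit = rng.standard_normal((n, n_lm, 3))
    if model.noise_corr_time_s > 0 and n > 1:
        # stationary AR(1): body-tracking error is temporally correlated,
        # not frame-independent; unit variance is preserved
        phi = math.exp(-1.0 / (model.rate_hz * model.noise_corr_time_s))
        from scipy.signal import lfilter

        w = unit * math.sqrt(1.0 - phi**2)
        w[0] = unit[0]
        unit = lfilter([1.0], [1.0, -phi], w, axis=0)
    sds = np.array(
        [
            model.noise_sd_mm.get(LANDMARK_CLASS.get(lm, "trunk"), 0.0)
            for lm in sensor.landmarks
        ]
    )
    mult = np.asarray(model.axis_multipliers, dtype=float)
    sensor.positions += (
        unit * (model.noise_scale * sds)[None, :, None] * mult[None, None, :]
    )
    sensor.positions += np.asarray(model.systematic_offset_mm, dtype=float)

    # dropout gaps: same draws regardless of the configured rate
    minutes = sensor.duration / 60.0
    max_gaps = 8
    gap_starts = rng.random((n_lm, max_gaps))
    gap_lens = rng.random((n_lm, max_gaps))
    gap_counts = rng.poisson(max(model.dropout_per_min, 0.0) * minutes, size=n_lm)
    if model.dropout_per_min > 0:
        max_len = max(1, int(model.dropout_max_ms / 1000.0 * model.rate_hz))
        for j in range(n_lm):
            for g in range(min(int(gap_counts[j]), max_gaps)):
                start = int(gap_starts[j, g] * (n - 1))
                length = 1 + int(gap_lens[j, g] * (max_len - 1))
                sensor.missing[start : start + length, j] = True
        sensor.positions[sensor.missing] = np.nan
    if sensor.missing.mean() > 0.5:
        raise DataError("dropout model produces >50% missing data")

    truth = RigidTransform(R.T, -R.T @ t_vec, -model.time_offset_s)
    sensor.meta["truth_transform"] = truth
    degraded = TaskRecording(
        task=reference.task,
        subject_id=reference.subject_id,
        repetition_index=reference.repetition_index,
        system=System.SENSOR,
        recording=sensor,
    )
    return degraded, truth


# ---------------------------------------------------------------------------
# population sampling for multi-subject studies
# ---------------------------------------------------------------------------

def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_subject_truths(rng: np.random.Generator) -> dict[Task, object]:
    """Draw one subject's task ground truths from population distributions
    with means and spreads on the scale reported for healthy adults
    (sway range ~1.3 deg, transition time ~1.5 s, stepping cadence
    ~90 steps/min, gait speed ~1.1 m/s, arm swing ~25 deg)."""
    pitch_amp = _trunc_normal(rng, 0.665, 0.2, 0.2, 1.5)
    roll_amp = _trunc_normal(rng, 0.375, 0.15, 0.1, 1.0)
    poco = PostureTruth(
        pitch_amp_deg=pitch_amp,
        roll_amp_deg=roll_amp,
        freq_hz=_trunc_normal(rng, 0.085, 0.02, 0.05, 0.12),
    )
    factor = logistic_threshold_duration(1.0)  # threshold duration per unit rise
    sas = SasTruth(
        rise_time_up_s=_trunc_normal(rng, 1.47, 0.23, 0.8, 2.2) / factor,
        rise_time_down_s=_trunc_normal(rng, 1.59, 0.22, 0.9, 2.3) / factor,
        ap_excursion_m=_trunc_normal(rng, 0.44, 0.10, 0.15, 0.75),
        hand_ap_range_m=_trunc_normal(rng, 0.39, 0.09, 0.12, 0.70),
    )
    cadence = _trunc_normal(rng, 88.2, 14.5, 55.0, 130.0)
    period = 2.0 * 60.0 / cadence
    duty = _trunc_normal(rng, 0.65, 0.05, 0.50, 0.75)
    sip = SipTruth(
        period_s=period,
        lift_m=_trunc_normal(rng, 0.24, 0.06, 0.10, 0.45),
        lift_duration_s=duty * period,
    )
    mean_arm = _trunc_normal(rng, 25.25, 8.0, 8.0, 45.0)
    delta = rng.normal(0.0, 15.0)  # degrees of arctangent asymmetry
    delta = float(np.clip(delta, -30.0, 30.0))
    ratio = math.tan(math.radians(45.0 + delta))
    amp_l = 2.0 * mean_arm * ratio / (1.0 + ratio)
    amp_r = 2.0 * mean_arm / (1.0 + ratio)
    gait = GaitTruth(
        speed_mps=_trunc_normal(rng, 1.11, 0.19, 0.6, 1.6),
        step_period_s=_trunc_normal(rng, 0.51, 0.04, 0.38, 0.68),
        arm_amp_l_deg=amp_l,
        arm_amp_r_deg=amp_r,
    )
    return {Task.POCO: poco, Task.SAS: sas, Task.SIP: sip, Task.SCSW: gait}
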