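"""Event detection and clinical parameter extraction for the four motor
tasks.

Tasks and their parameter sets
------------------------------
POCO (quiet stance)
    Angular body sway: the sway vector runs from the mean of both ankle
    landmarks to the spine base.  Its sagittal (pitch) and frontal (roll)
    inclinations yield range [deg] and mean absolute sway speed [deg/s] in
    pitch, roll and 3D.
SAS (stand up and sit down)
    Transition times from the vertical spine-shoulder trajectory plus
    anterior-posterior deflection ranges of the upper body and hands
    during each transition, per direction (up / down).
SIP (stepping in place)
    Step events from the knees' planar (AP-V) displacement: step count,
    cadence, mean step time, mean stance time, knee movement amplitude.
SCSW (short comfortable-speed walk toward the sensor)
    Gait speed, foot-contact based step length / duration / cadence, and
    arm swing amplitude / symmetry angle.

Across the four tasks, 23 canonical parameters are produced (see
:data:`PARAMETER_SCHEMA`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal as sps

from .skeleton import AXIS_AP, AXIS_ML, AXIS_V, DataError, SkeletonRecording, Task

__all__ = [
    "PARAMETER_SCHEMA",
    "PARAMETER_UNITS",
    "SwaySeries",
    "TransitionEvent",
    "StepEvent",
    "ParameterSet",
    "sway_angles",
    "posture_parameters",
    "detect_transitions",
    "sas_parameters",
    "detect_sip_steps",
    "sip_parameters",
    "detect_gait_events",
    "gait_parameters",
    "symmetry_angle",
    "extract_parameters",
]

#: Canonical parameter names per task.  The 23 entries of this schema are
#: the full published parameter set; ``scsw_step_count`` is additionally
#: computed but reported as an auxiliary quantity.
PARAMETER_SCHEMA: dict[Task, tuple[str, ...]] = {
    Task.POCO: (
        "pitch_sway_range_deg",
        "roll_sway_range_deg",
        "sway_range_3d_deg",
        "pitch_sway_speed_dps",
        "roll_sway_speed_dps",
        "sway_speed_3d_dps",
    ),
    Task.SAS: (
        "transition_time_up_s",
        "transition_time_down_s",
        "ap_deflection_range_up_m",
        "ap_deflection_range_down_m",
        "hand_ap_range_up_m",
        "hand_ap_range_down_m",
    ),
    Task.SIP: (
        "knee_amplitude_cm",
        "step_count",
        "cadence_steps_per_min",
        "step_time_s",
        "stance_time_s",
    ),
    Task.SCSW: (
        "gait_speed_mps",
        "step_length_cm",
        "cadence_steps_per_min",
        "step_duration_s",
        "arm_amplitude_deg",
        "arm_symmetry_angle",
    ),
}

PARAMETER_UNITS: dict[str, str] = {
    "pitch_sway_range_deg": "deg",
    "roll_sway_range_deg": "deg",
    "sway_range_3d_deg": "deg",
    "pitch_sway_speed_dps": "deg/s",
    "roll_sway_speed_dps": "deg/s",
    "sway_speed_3d_dps": "deg/s",
    "transition_time_up_s": "s",
    "transition_time_down_s": "s",
    "ap_deflection_range_up_m": "m",
    "ap_deflection_range_down_m": "m",
    "hand_ap_range_up_m": "m",
    "hand_ap_range_down_m": "m",
    "knee_amplitude_cm": "cm",
    "step_count": "count",
    "cadence_steps_per_min": "steps/min",
    "step_time_s": "s",
    "stance_time_s": "s",
    "gait_speed_mps": "m/s",
    "step_length_cm": "cm",
    "step_duration_s": "s",
    "arm_amplitude_deg": "deg",
    "arm_symmetry_angle": "n.u.",
    "scsw_step_count": "count",
}


class TransitionKind(str, Enum):
    STAND_UP = "STAND_UP"
    SIT_DOWN = "SIT_DOWN"


@dataclass
class SwaySeries:
    """Sagittal / frontal inclination of the sway vector over time."""

    timestamps: np.ndarray
    pitch_deg: np.ndarray
    roll_deg: np.ndarray


@dataclass
class TransitionEvent:
    kind: TransitionKind
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class StepEvent:
    side: str  # "l" or "r"
    peak_time_s: float
    lift_time_s: float | None = None
    land_time_s: float | None = None
    prominence_mm: float | None = None


@dataclass
class ParameterSet:
    """Named clinical parameters of one task recording, with units."""

    task: Task
    values: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_dict(self) -> dict:
        return {
            "task": self.task.value,
            "values": {k: float(v) for k, v in self.values.items()},
            "units": {k: PARAMETER_UNITS.get(k, "") for k in self.values},
            "flags": list(self.flags),
        }


def _require(rec: SkeletonRecording, landmarks: list[str], max_missing: float = 0.10):
    for lm in landmarks:
        frac = rec.get_missing(lm).mean() if rec.n_frames else 1.0
        if frac > max_missing:
            raise DataError(f"landmark {lm!r} missing in {frac:.0%} of frames")


# ---------------------------------------------------------------------------
# POCO — postural control
# ---------------------------------------------------------------------------

def sway_angles(rec: SkeletonRecording) -> SwaySeries:
    """Sway vector angles: spine base relative to the per-frame mean ankle
    position.  Pitch = atan2(AP, V), roll = atan2(ML, V), degrees."""
    _require(rec, ["spine_base", "ankle_l", "ankle_r"])
    base = rec.get("spine_base")
    anchor = 0.5 * (rec.get("ankle_l") + rec.get("ankle_r"))
    vec = base - anchor
    pitch = np.degrees(np.arctan2(vec[:, AXIS_AP], vec[:, AXIS_V]))
    roll = np.degrees(np.arctan2(vec[:, AXIS_ML], vec[:, AXIS_V]))
    if np.nanmax(np.abs(pitch)) >= 90 or np.nanmax(np.abs(roll)) >= 90:
        raise DataError("implausible sway angle >= 90 deg")
    return SwaySeries(rec.timestamps.copy(), pitch, roll)


def _trajectory_diameter(points: np.ndarray) -> float:
    """Largest pairwise distance of a 2D point cloud (hull-accelerated,
    with a principal-axis fallback for degenerate clouds)."""
    if points.shape[0] < 2:
        return 0.0
    try:
        from scipy.spatial import ConvexHull

        hull = points[ConvexHull(points).vertices]
    except Exception:  # collinear / constant trajectories
        centred = points - points.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        proj = centred @ vt[0]
        return float(proj.max() - proj.min())
    d = hull[:, None, :] - hull[None, :, :]
    return float(np.sqrt((d**2).sum(-1)).max())


def posture_parameters(sway: SwaySeries, duration_s: float | None = None) -> ParameterSet:
    """Sway range (max - min) and mean absolute sway speed per component.

    The 3D deflection range is the angular diameter of the sway
    trajectory in the (roll, pitch) plane — the largest angular
    separation reached between any two sway orientations.  It reduces to
    the component range when sway is confined to one plane.  The 3D speed
    is the mean magnitude of the (pitch, roll) angular velocity.
    """
    t = sway.timestamps
    if t.size < 2:
        raise DataError("need >= 2 frames for sway parameters")
    ok = np.isfinite(sway.pitch_deg) & np.isfinite(sway.roll_deg)
    t, pitch, roll = t[ok], sway.pitch_deg[ok], sway.roll_deg[ok]
    dpitch = np.diff(pitch)
    droll = np.diff(roll)
    total = t[-1] - t[0]
    ps = ParameterSet(Task.POCO)
    ps.values = {
        "pitch_sway_range_deg": float(pitch.max() - pitch.min()),
        "roll_sway_range_deg": float(roll.max() - roll.min()),
        "sway_range_3d_deg": _trajectory_diameter(np.column_stack([roll, pitch])),
        "pitch_sway_speed_dps": float(np.sum(np.abs(dpitch)) / total),
        "roll_sway_speed_dps": float(np.sum(np.abs(droll)) / total),
        "sway_speed_3d_dps": float(np.sum(np.hypot(dpitch, droll)) / total),
    }
    return ps


# ---------------------------------------------------------------------------
# SAS — stand up and sit down
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, t: np.ndarray, rate: float, cutoff: float = 2.0) -> np.ndarray:
    b, a = sps.butter(2, cutoff, btype="low", fs=rate)
    padlen = 3 * max(len(a), len(b))
    if y.size <= padlen:
        return y
    return sps.filtfilt(b, a, y)


def detect_transitions(
    rec: SkeletonRecording,
    speed_fraction: float = 0.10,
    min_rise_mm: float = 100.0,
) -> list[TransitionEvent]:
    """Detect stand-up / sit-down transitions from the vertical
    spine-shoulder trajectory.

    Vertical speed peaks (rising = STAND_UP, falling = SIT_DOWN) are
    bracketed by the crossings of ``speed_fraction`` of each peak's speed,
    which define the transition start and end.
    """
    _require(rec, ["spine_shoulder"])
    y_raw = rec.get("spine_shoulder")[:, AXIS_V]
    ok = np.isfinite(y_raw)
    if ok.sum() < 10 or (np.nanmax(y_raw) - np.nanmin(y_raw)) < min_rise_mm:
        return []
    # detect on a uniform grid: timestamp jitter would otherwise leak
    # multiplicative noise into the speed estimate and bias its peak
    dt = 1.0 / rec.nominal_rate
    span = rec.timestamps[-1] - rec.timestamps[0]
    t = rec.timestamps[0] + dt * np.arange(int(span / dt) + 1)
    y = np.interp(t, rec.timestamps[ok], y_raw[ok])
    y_s = _smooth(y, t, rec.nominal_rate)
    v = np.gradient(y_s, t)
    speed = np.abs(v)
    vmax = speed.max()
    if vmax <= 0:
        return []
    # speed peaks of individual transitions
    min_dist = max(1, int(0.8 * rec.nominal_rate))
    peaks, _ = sps.find_peaks(speed, height=0.3 * vmax, distance=min_dist)
    events: list[TransitionEvent] = []
    for p in peaks:
        thr = speed_fraction * speed[p]
        i = p
        while i > 0 and speed[i - 1] > thr and np.sign(v[i - 1]) == np.sign(v[p]):
            i -= 1
        j = p
        n = speed.size
        while j < n - 1 and speed[j + 1] > thr and np.sign(v[j + 1]) == np.sign(v[p]):
            j += 1
        # sub-frame refinement of the threshold crossings
        t_start = float(t[i])
        if i > 0 and speed[i - 1] <= thr < speed[i]:
            frac = (thr - speed[i - 1]) / (speed[i] - speed[i - 1])
            t_start = float(t[i - 1] + frac * (t[i] - t[i - 1]))
        t_end = float(t[j])
        if j < n - 1 and speed[j + 1] <= thr < speed[j]:
            frac = (speed[j] - thr) / (speed[j] - speed[j + 1])
            t_end = float(t[j] + frac * (t[j + 1] - t[j]))
        kind = TransitionKind.STAND_UP if v[p] > 0 else TransitionKind.SIT_DOWN
        events.append(TransitionEvent(kind, t_start, t_end))
    # merge overlapping fragments of the same transition
    merged: list[TransitionEvent] = []
    for ev in sorted(events, key=lambda e: e.start_s):
        if merged and ev.kind == merged[-1].kind and ev.start_s <= merged[-1].end_s:
            merged[-1] = TransitionEvent(
                ev.kind, merged[-1].start_s, max(merged[-1].end_s, ev.end_s)
            )
        else:
            merged.append(ev)
    return merged


def sas_parameters(
    rec: SkeletonRecording, events: list[TransitionEvent]
) -> ParameterSet:
    """Mean transition time, upper-body AP deflection range and hand AP
    range per transition direction."""
    kinds = {e.kind for e in events}
    if TransitionKind.STAND_UP not in kinds or TransitionKind.SIT_DOWN not in kinds:
        raise DataError("need at least one transition of each kind")
    t = rec.timestamps
    shoulder_ap = rec.get("spine_shoulder")[:, AXIS_AP]
    hand_ap = {s: rec.get(f"hand_{s}")[:, AXIS_AP] for s in ("l", "r")}
    ps = ParameterSet(Task.SAS)
    for kind, tag in ((TransitionKind.STAND_UP, "up"), (TransitionKind.SIT_DOWN, "down")):
        evs = [e for e in events if e.kind == kind]
        durations, deflections, hand_ranges = [], [], []
        for e in evs:
            win = (t >= e.start_s) & (t <= e.end_s)
            if not win.any():
                raise DataError("event window outside recording")
            durations.append(e.duration_s)
            seg = shoulder_ap[win]
            seg = seg[np.isfinite(seg)]
            deflections.append((seg.max() - seg.min()) / 1000.0)
            per_hand = []
            for s in ("l", "r"):
                h = hand_ap[s][win]
                h = h[np.isfinite(h)]
                per_hand.append((h.max() - h.min()) / 1000.0)
            hand_ranges.append(float(np.mean(per_hand)))
        ps.values[f"transition_time_{tag}_s"] = float(np.mean(durations))
        ps.values[f"ap_deflection_range_{tag}_m"] = float(np.mean(deflections))
        ps.values[f"hand_ap_range_{tag}_m"] = float(np.mean(hand_ranges))
    return ps


# ---------------------------------------------------------------------------
# SIP — stepping in place
# ---------------------------------------------------------------------------

def _knee_displacement(rec: SkeletonRecording, side: str, planar: bool = True) -> np.ndarray:
    """Knee displacement signal relative to its grounded baseline.

    The vertical baseline is the 10th percentile of the vertical
    coordinate (the knee rests there between lifts).  The AP baseline is
    the median AP position over grounded frames (low vertical excursion),
    since the forward lift excursion would otherwise shift a plain
    percentile off the rest position.  Planar (AP-V) magnitude by default;
    AP-only available via ``planar``.
    """
    knee = rec.get(f"knee_{side}")
    ap = knee[:, AXIS_AP]
    v = knee[:, AXIS_V]
    ok = np.isfinite(ap) & np.isfinite(v)
    v0 = np.percentile(v[ok], 10)
    v_rel = v - v0
    v_amp = np.percentile(v_rel[ok], 98)
    grounded = ok & (v_rel < 0.2 * max(v_amp, 1e-9))
    ap0 = np.median(ap[grounded]) if grounded.any() else np.percentile(ap[ok], 10)
    d_ap = ap - ap0
    if not planar:
        return np.abs(d_ap)
    return np.hypot(d_ap, v_rel)


def detect_sip_steps(
    rec: SkeletonRecording,
    prominence_fraction: float = 0.25,
    min_gap_s: float = 0.3,
    noise_floor_mm: float = 30.0,
    planar: bool = True,
) -> list[StepEvent]:
    """Step events per knee from the planar knee-displacement signal.

    Steps are local maxima with prominence >= ``prominence_fraction`` of
    that knee's movement amplitude and >= ``min_gap_s`` apart; lift and
    land times are the 20%-of-peak crossings around each maximum.
    """
    _require(rec, ["knee_l", "knee_r"])
    t = rec.timestamps
    events: list[StepEvent] = []
    for side in ("l", "r"):
        sig = _knee_displacement(rec, side, planar=planar)
        ok = np.isfinite(sig)
        sig = np.interp(t, t[ok], sig[ok])
        amp = float(np.percentile(sig, 98))
        if amp < noise_floor_mm:
            continue  # below noise floor: no steps for this knee
        dist = max(1, int(round(min_gap_s * rec.nominal_rate)))
        peaks, props = sps.find_peaks(
            sig, prominence=prominence_fraction * amp, distance=dist
        )
        for p, prom in zip(peaks, props["prominences"]):
            thr = 0.2 * sig[p]
            i = p
            while i > 0 and sig[i - 1] > thr:
                i -= 1
            j = p
            while j < sig.size - 1 and sig[j + 1] > thr:
                j += 1
            events.append(
                StepEvent(
                    side=side,
                    peak_time_s=float(t[p]),
                    lift_time_s=float(t[i]),
                    land_time_s=float(t[j]),
                    prominence_mm=float(prom),
                )
            )
    events.sort(key=lambda e: e.peak_time_s)
    return events


def sip_parameters(
    rec: SkeletonRecording,
    events: list[StepEvent],
    duration_s: float | None = None,
) -> ParameterSet:
    """Cadence, step count, mean step / stance time and knee amplitude."""
    if len(events) < 4:
        raise DataError("need >= 4 step events")
    duration = duration_s if duration_s is not None else rec.duration
    times = np.array([e.peak_time_s for e in events])
    step_times = np.diff(times)
    stance: list[float] = []
    for side in ("l", "r"):
        evs = [e for e in events if e.side == side]
        for prev, nxt in zip(evs, evs[1:]):
            if prev.land_time_s is not None and nxt.lift_time_s is not None:
                stance.append(nxt.lift_time_s - prev.land_time_s)
    proms = [e.prominence_mm for e in events if e.prominence_mm is not None]
    ps = ParameterSet(Task.SIP)
    ps.values = {
        "knee_amplitude_cm": float(np.mean(proms) / 10.0) if proms else math.nan,
        "step_count": float(len(events)),
        "cadence_steps_per_min": float(len(events) / duration * 60.0),
        "step_time_s": float(np.mean(step_times)),
        "stance_time_s": float(np.mean(stance)) if stance else math.nan,
    }
    if not stance:
        ps.flags.append("stance time undefined (too few same-side events)")
    return ps


# ---------------------------------------------------------------------------
# SCSW — short comfortable-speed walk
# ---------------------------------------------------------------------------

def _progression_sign(rec: SkeletonRecording) -> float:
    base_ap = rec.get("spine_base")[:, AXIS_AP]
    ok = np.isfinite(base_ap)
    return -1.0 if base_ap[ok][-1] < base_ap[ok][0] else 1.0


def detect_gait_events(
    rec: SkeletonRecording,
    prominence_fraction: float = 0.25,
    min_gap_s: float = 0.3,
) -> list[StepEvent]:
    """Foot contacts per side: local maxima of the ankle-ahead-of-pelvis
    excursion (ankle AP minus spine base AP, signed along progression)."""
    _require(rec, ["spine_base", "ankle_l", "ankle_r"])
    t = rec.timestamps
    d = _progression_sign(rec)
    base_ap = rec.get("spine_base")[:, AXIS_AP]
    events: list[StepEvent] = []
    dist = max(1, int(round(min_gap_s * rec.nominal_rate)))
    for side in ("l", "r"):
        rel = (rec.get(f"ankle_{side}")[:, AXIS_AP] - base_ap) * d
        ok = np.isfinite(rel)
        rel = np.interp(t, t[ok], rel[ok])
        # band-limit before peak finding so jitter cannot move contacts
        rel = _smooth(rel, t, rec.nominal_rate, cutoff=3.0)
        spread = np.percentile(rel, 95) - np.percentile(rel, 5)
        if spread <= 0:
            continue
        peaks, _ = sps.find_peaks(
            rel, prominence=prominence_fraction * spread, distance=dist
        )
        events.extend(StepEvent(side=side, peak_time_s=float(t[p])) for p in peaks)
    events.sort(key=lambda e: e.peak_time_s)
    return events


def symmetry_angle(amp_left_deg: float, amp_right_deg: float) -> float:
    """Bilateral symmetry angle: |45deg - atan(L/R)| / 90deg, in [0, 0.5].

    0 means perfect left/right symmetry; invariant to swapping sides.
    """
    if amp_left_deg <= 0 or amp_right_deg <= 0:
        raise DataError("symmetry angle undefined for non-positive amplitude")
    return float(
        abs(45.0 - math.degrees(math.atan(amp_left_deg / amp_right_deg))) / 90.0
    )


def _arm_angle_deg(rec: SkeletonRecording, side: str, d: float) -> np.ndarray:
    """Sagittal inclination of the spine-shoulder -> wrist vector, degrees
    (positive = wrist ahead of the trunk along progression)."""
    vec = rec.get(f"wrist_{side}") - rec.get("spine_shoulder")
    return np.degrees(np.arctan2(vec[:, AXIS_AP] * d, -vec[:, AXIS_V]))


def gait_parameters(
    rec: SkeletonRecording,
    events: list[StepEvent],
    steady_fraction: float = 0.8,
) -> ParameterSet:
    """Spatiotemporal gait parameters from a walk toward the sensor.

    Gait speed needs no gait-cycle detection (spine-base AP displacement
    over the central ``steady_fraction`` of the walk) and is always
    returned.  With fewer than 2 foot contacts the cycle-based parameters
    are reported as NaN and flagged — mirroring sensors whose usable walk
    path is too short to cover enough gait cycles.
    """
    _require(rec, ["spine_base"])
    t = rec.timestamps
    d = _progression_sign(rec)
    base_ap = rec.get("spine_base")[:, AXIS_AP]
    ok = np.isfinite(base_ap)
    t_ok, ap_ok = t[ok], base_ap[ok]
    span = t_ok[-1] - t_ok[0]
    margin = (1.0 - steady_fraction) / 2.0 * span
    w0, w1 = t_ok[0] + margin, t_ok[-1] - margin
    ap_w0 = np.interp(w0, t_ok, ap_ok)
    ap_w1 = np.interp(w1, t_ok, ap_ok)
    speed = abs(ap_w1 - ap_w0) / (w1 - w0) / 1000.0  # m/s
    ps = ParameterSet(Task.SCSW)
    ps.values["gait_speed_mps"] = float(speed)
    ps.values["scsw_step_count"] = float(len(events))
    if len(events) < 2:
        for name in (
            "step_length_cm",
            "cadence_steps_per_min",
            "step_duration_s",
            "arm_amplitude_deg",
            "arm_symmetry_angle",
        ):
            ps.values[name] = math.nan
        ps.flags.append("too few gait cycles for spatiotemporal parameters")
        return ps
    times = np.array([e.peak_time_s for e in events])
    step_dur = float(np.mean(np.diff(times)))
    ap_at_contacts = np.interp(times, t_ok, ap_ok)
    step_len_cm = float(np.mean(np.abs(np.diff(ap_at_contacts))) / 10.0)
    amps = {}
    for side in ("l", "r"):
        theta = _arm_angle_deg(rec, side, d)
        okt = np.isfinite(theta)
        theta_i = np.interp(t, t[okt], theta[okt])
        side_times = [e.peak_time_s for e in events if e.side == side]
        cycle_amps = []
        for a, b in zip(side_times, side_times[1:]):
            win = (t >= a) & (t <= b)
            if win.sum() >= 3:
                seg = theta_i[win]
                cycle_amps.append((seg.max() - seg.min()) / 2.0)
        if cycle_amps:
            amps[side] = float(np.mean(cycle_amps))
        else:  # fall back to the global half-range
            amps[side] = float((theta_i.max() - theta_i.min()) / 2.0)
    ps.values.update(
        {
            "step_duration_s": step_dur,
            "cadence_steps_per_min": 60.0 / step_dur,
            "step_length_cm": step_len_cm,
            "arm_amplitude_deg": float((amps["l"] + amps["r"]) / 2.0),
            "arm_symmetry_angle": symmetry_angle(amps["l"], amps["r"]),
        }
    )
    return ps


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def extract_parameters(rec: SkeletonRecording, task: Task) -> ParameterSet:
    """Run the task-appropriate event detection and parameter extraction."""
    task = Task(task)
    if task is Task.POCO:
        return posture_parameters(sway_angles(rec))
    if task is Task.SAS:
        return sas_parameters(rec, detect_transitions(rec))
    if task is Task.SIP:
        return sip_parameters(rec, detect_sip_steps(rec))
    if task is Task.SCSW:
        return gait_parameters(rec, detect_gait_events(rec))
    raise ValueError(task)
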