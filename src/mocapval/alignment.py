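"""Spatial and temporal alignment of sensor recordings onto the reference
frame: signed axis permutations, sensor-tilt compensation, rigid
(Kabsch/Procrustes) registration and timestamp-offset estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import sample_at
from .skeleton import (
    AXIS_AP,
    AXIS_V,
    CANONICAL_AXES,
    DataError,
    SkeletonRecording,
    TRUNK_LANDMARKS,
)

__all__ = [
    "RigidTransform",
    "signed_permutation_matrix",
    "normalize_axes",
    "tilt_compensation",
    "estimate_rigid_transform",
    "apply_transform",
    "OffsetEstimate",
    "temporal_offset_from_timestamps",
    "register_recordings",
]


@dataclass
class RigidTransform:
    """Rotation + translation (+ temporal offset) mapping one coordinate
    frame onto another: ``x -> R x + t``, ``time -> time + time_offset``."""

    rotation: np.ndarray
    translation: np.ndarray
    time_offset: float = 0.0
    residual_rms_mm: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise DataError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, -self.time_offset)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            self.time_offset + other.time_offset,
        )

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation_mm": self.translation.tolist(),
            "time_offset_s": self.time_offset,
            "residual_rms_mm": self.residual_rms_mm,
        }


def signed_permutation_matrix(axes: tuple[str, str, str]) -> np.ndarray:
    """Build a signed permutation matrix from axis labels.

    ``axes[i]`` names the source axis (optionally sign-prefixed) that
    becomes output axis i, e.g. ``("x", "-z", "y")`` means new_y = -old_z.
    """
    index = {"x": 0, "y": 1, "z": 2}
    M = np.zeros((3, 3))
    for i, token in enumerate(axes):
        token = token.strip()
        sign = 1.0
        if token[0] in "+-":
            sign = -1.0 if token[0] == "-" else 1.0
            token = token[1:]
        if token not in index:
            raise DataError(f"invalid axis token {token!r}")
        M[i, index[token]] = sign
    if abs(abs(np.linalg.det(M)) - 1.0) > 1e-12 or np.any(
        np.abs(M).sum(axis=0) != 1
    ):
        raise DataError("axes is not a signed axis permutation")
    return M


def normalize_axes(
    rec: SkeletonRecording, axes: tuple[str, str, str] | np.ndarray
) -> SkeletonRecording:
    """Relabel axes by a signed permutation so the output follows the
    canonical x=ML, y=V, z=AP convention."""
    M = axes if isinstance(axes, np.ndarray) else signed_permutation_matrix(axes)
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3) or abs(abs(np.linalg.det(M)) - 1.0) > 1e-9:
        raise DataError("not a signed permutation matrix")
    sums = np.abs(M).sum(axis=0)
    if not np.allclose(sums, 1.0) or not np.all(np.isin(np.abs(M), (0.0, 1.0))):
        raise DataError("not a signed permutation matrix")
    out = rec.copy()
    out.positions = rec.positions @ M.T
    out.axis_convention = CANONICAL_AXES
    return out


def tilt_compensation(
    rec: SkeletonRecording, floor_normal: np.ndarray
) -> SkeletonRecording:
    """Rotate positions so the measured floor normal becomes vertical (+V).

    The minimal (axis-angle) rotation is used, so no yaw about the vertical
    is introduced beyond it.  A floor normal with no vertical component
    (e.g. parallel to AP) is degenerate and rejected.
    """
    n = np.asarray(floor_normal, dtype=float).reshape(3)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise DataError("floor normal must be non-zero")
    n = n / norm
    if n[AXIS_V] <= 1e-9:
        raise DataError("degenerate floor normal (no upward component)")
    up = np.zeros(3)
    up[AXIS_V] = 1.0
    axis = np.cross(n, up)
    s = np.linalg.norm(axis)
    c = float(n @ up)
    out = rec.copy()
    if s < 1e-12:
        return out  # already level
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    theta = np.arctan2(s, c)
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    out.positions = rec.positions @ R.T
    return out


def estimate_rigid_transform(
    src_points: np.ndarray,
    dst_points: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Least-squares rigid transform (Kabsch) taking src onto dst.

    Points are ``(n, 3)`` arrays of paired coordinates; a proper rotation
    is enforced via the SVD sign correction.  The weighted residual RMS is
    stored on the returned transform.
    """
    src = np.asarray(src_points, dtype=float).reshape(-1, 3)
    dst = np.asarray(dst_points, dtype=float).reshape(-1, 3)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise DataError("need >= 3 paired points")
    if weights is None:
        w = np.ones(src.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (src.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise DataError("invalid weights")
    w = w / w.sum()
    mu_s = w @ src
    mu_d = w @ dst
    xs = src - mu_s
    xd = dst - mu_d
    H = (xs * w[:, None]).T @ xd
    U, S, Vt = np.linalg.svd(H)
    # degenerate (e.g. collinear) configurations leave the rotation
    # under-determined about the point axis
    if S[1] <= 1e-9 * max(S[0], 1.0):
        raise DataError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    resid = dst - (src @ R.T + t)
    rms = float(np.sqrt(np.sum(w * np.sum(resid**2, axis=1))))
    return RigidTransform(R, t, 0.0, rms)


def apply_transform(rec: SkeletonRecording, tf: RigidTransform) -> SkeletonRecording:
    """Map positions through ``x -> R x + t`` and shift timestamps by the
    transform's temporal offset."""
    out = rec.copy()
    out.positions = rec.positions @ tf.rotation.T + tf.translation
    out.positions[rec.missing] = np.nan
    out.timestamps = rec.timestamps + tf.time_offset
    return out


@dataclass
class OffsetEstimate:
    offset_s: float
    refined: bool
    fallback: bool = False
    note: str = ""


def temporal_offset_from_timestamps(
    ref_rec: SkeletonRecording,
    sensor_rec: SkeletonRecording,
    declared_offset_s: float,
    refine: bool = False,
    search_s: float = 0.2,
    landmark: str = "spine_base",
    min_motion_mm: float = 15.0,
) -> OffsetEstimate:
    """Temporal offset of the sensor clock relative to the reference.

    The declared offset (system-timestamp difference) is returned as-is
    unless ``refine`` is set, in which case it is adjusted by maximizing
    the cross-correlation of the spine-base AP velocity within
    ``±search_s``.  Refinement on a near-static signal (quiet stance) is
    unreliable and falls back to the declared offset, flagged.
    """
    if ref_rec.n_frames == 0 or sensor_rec.n_frames == 0:
        raise DataError("empty recording")
    if not refine:
        return OffsetEstimate(declared_offset_s, refined=False)
    ap_sen = sensor_rec.get(landmark)[:, AXIS_AP]
    if np.std(ap_sen[np.isfinite(ap_sen)]) < min_motion_mm:
        return OffsetEstimate(
            declared_offset_s,
            refined=False,
            fallback=True,
            note="near-static signal; cross-correlation unreliable",
        )
    rate = sensor_rec.nominal_rate
    dt = 1.0 / rate
    # velocity series on a common grid, sensor shifted by the declared offset
    t_sen = sensor_rec.timestamps - declared_offset_s
    lags = np.arange(-search_s, search_s + dt / 2, dt)
    t_ref = ref_rec.timestamps
    ap_ref = ref_rec.get(landmark)[:, AXIS_AP]
    ok_ref = np.isfinite(ap_ref)
    ok_sen = np.isfinite(ap_sen)
    v_sen = np.gradient(ap_sen[ok_sen], t_sen[ok_sen])
    t_s = t_sen[ok_sen]
    best_lag, best_score = 0.0, -np.inf
    for lag in lags:
        ts = t_s + lag
        inside = (ts >= t_ref[ok_ref][0]) & (ts <= t_ref[ok_ref][-1])
        if inside.sum() < 10:
            continue
        v_ref = np.gradient(
            np.interp(ts[inside], t_ref[ok_ref], ap_ref[ok_ref]), ts[inside]
        )
        a = v_sen[inside] - v_sen[inside].mean()
        b = v_ref - v_ref.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom == 0:
            continue
        score = float(a @ b / denom)
        if score > best_score:
            best_score, best_lag = score, float(lag)
    # a positive best lag means the sensor led the reference after the
    # declared shift, i.e. the true offset is smaller
    return OffsetEstimate(declared_offset_s - best_lag, refined=True)


def register_recordings(
    ref_rec: SkeletonRecording,
    sensor_rec: SkeletonRecording,
    landmarks: tuple[str, ...] = TRUNK_LANDMARKS,
    time_offset_s: float = 0.0,
) -> RigidTransform:
    """Estimate the rigid transform taking the sensor frame onto the
    reference frame.

    The reference is linearly interpolated at the (offset-corrected)
    sensor timestamps, and the Kabsch solution is pooled over all frames
    where the chosen calibration landmarks are present in both systems.
    The registration subset defaults to trunk landmarks, which carry the
    least tracking noise.
    """
    t_sen = sensor_rec.timestamps - time_offset_s
    lo = max(t_sen[0], ref_rec.timestamps[0])
    hi = min(t_sen[-1], ref_rec.timestamps[-1])
    inside = (t_sen >= lo) & (t_sen <= hi)
    if inside.sum() < 2:
        raise DataError("no temporal overlap for registration")
    ref_at = sample_at(ref_rec, t_sen[inside])
    idx_ref = [ref_at.index(lm) for lm in landmarks]
    idx_sen = [sensor_rec.index(lm) for lm in landmarks]
    src = sensor_rec.positions[inside][:, idx_sen, :]
    dst = ref_at.positions[:, idx_ref, :]
    ok = ~(sensor_rec.missing[inside][:, idx_sen] | ref_at.missing[:, idx_ref])
    tf = estimate_rigid_transform(src[ok], dst[ok])
    tf.time_offset = -time_offset_s
    return tf
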