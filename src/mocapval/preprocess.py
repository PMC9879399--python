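"""Trajectory preprocessing: gap interpolation, low-pass filtering,
resampling and overlap trimming.

The pipeline order is gaps -> filter -> resample (reference only) -> trim.
Filtering is zero-phase (forward-backward), so the effective magnitude
response is the squared single-pass first-order Butterworth magnitude and
no phase lag is introduced — event timing downstream is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .skeleton import DataError, SkeletonRecording

__all__ = [
    "PreprocessConfig",
    "interpolate_short_gaps",
    "lowpass",
    "resample_to",
    "sample_at",
    "trim_to_overlap",
    "pair_frames",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the preprocessing stage.

    max_gap_ms
        Gaps strictly shorter than this are spline-interpolated (56 ms
        corresponds to 10 frames at 178 Hz marker flicker).
    cutoff_hz / filter_order
        Butterworth low-pass design; first order at 5 Hz keeps voluntary
        movement while suppressing tracking jitter.
    target_rate_hz
        Grid rate for downsampling the high-rate reference recordings to
        the sensor rate.
    """

    max_gap_ms: float = 56.0
    spline_order: int = 3
    cutoff_hz: float = 5.0
    filter_order: int = 1
    zero_phase: bool = True
    target_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if self.max_gap_ms <= 0:
            raise ValueError("max_gap_ms must be positive")
        if not 0 < self.cutoff_hz < self.target_rate_hz / 2:
            raise ValueError("cutoff_hz must lie in (0, target_rate/2)")


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs (stop exclusive)."""
    runs: list[tuple[int, int]] = []
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def interpolate_short_gaps(
    rec: SkeletonRecording, cfg: PreprocessConfig = PreprocessConfig()
) -> SkeletonRecording:
    """Fill missing runs shorter than ``cfg.max_gap_ms`` by spline
    interpolation through the flanking valid samples.

    Edge gaps (no valid sample on one side) and runs at or above the
    threshold are left missing.  Non-missing samples are never altered.
    Landmarks that are missing throughout are reported in
    ``meta['unfillable_landmarks']`` and left untouched.
    """
    out = rec.copy()
    t = rec.timestamps
    dt = 1.0 / rec.nominal_rate
    max_gap_s = cfg.max_gap_ms / 1000.0
    unfillable: list[str] = []
    for j, lm in enumerate(rec.landmarks):
        mask = rec.missing[:, j]
        if not mask.any():
            continue
        valid = ~mask
        if valid.sum() == 0:
            unfillable.append(lm)
            continue
        t_valid = t[valid]
        k = min(cfg.spline_order, valid.sum() - 1)
        k = max(k, 1)
        splines = [
            interpolate.make_interp_spline(t_valid, rec.positions[valid, j, a], k=k)
            for a in range(3)
        ]
        for start, stop in _missing_runs(mask):
            if start == 0 or stop == rec.n_frames:
                continue  # no extrapolation at the edges
            # gap duration = time spanned by the missing frames themselves
            gap_s = t[stop] - t[start - 1] - dt
            if gap_s >= max_gap_s:
                continue
            for a in range(3):
                out.positions[start:stop, j, a] = splines[a](t[start:stop])
            out.missing[start:stop, j] = False
    if unfillable:
        out.meta.setdefault("unfillable_landmarks", []).extend(unfillable)
    return out


def _segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous valid runs as (start, stop) index pairs."""
    return _missing_runs(valid)


def lowpass(
    rec: SkeletonRecording, cfg: PreprocessConfig = PreprocessConfig()
) -> SkeletonRecording:
    """Butterworth low-pass of every landmark axis, per contiguous valid
    segment.  Segments too short for the filter warm-up are returned
    unfiltered and flagged in ``meta['unfiltered_segments']``."""
    out = rec.copy()
    b, a = signal.butter(
        cfg.filter_order, cfg.cutoff_hz, btype="low", fs=rec.nominal_rate
    )
    padlen = 3 * max(len(a), len(b))
    skipped = 0
    for j in range(len(rec.landmarks)):
        valid = ~rec.missing[:, j]
        for start, stop in _segments(valid):
            seg = rec.positions[start:stop, j, :]
            if stop - start <= padlen:
                skipped += 1
                continue
            if cfg.zero_phase:
                out.positions[start:stop, j, :] = signal.filtfilt(
                    b, a, seg, axis=0
                )
            else:
                out.positions[start:stop, j, :] = signal.lfilter(b, a, seg, axis=0)
    if skipped:
        out.meta["unfiltered_segments"] = out.meta.get("unfiltered_segments", 0) + skipped
    return out


def sample_at(rec: SkeletonRecording, times: np.ndarray) -> SkeletonRecording:
    """Linearly interpolate all landmarks at the given times.

    Times must lie inside the recording span.  Output samples are flagged
    missing if either flanking source sample is missing.
    """
    times = np.asarray(times, dtype=float)
    t = rec.timestamps
    if rec.n_frames < 2:
        raise DataError("need at least 2 frames to interpolate")
    if times.size and (times[0] < t[0] - 1e-12 or times[-1] > t[-1] + 1e-12):
        raise DataError("requested times outside the recording span")
    n_lm = len(rec.landmarks)
    pos = np.empty((times.size, n_lm, 3))
    miss = np.zeros((times.size, n_lm), dtype=bool)
    for j in range(n_lm):
        for a in range(3):
            pos[:, j, a] = np.interp(times, t, rec.positions[:, j, a])
        # a target sample is missing if any mass of the missing indicator
        # bleeds into it from either neighbour
        miss[:, j] = np.interp(times, t, rec.missing[:, j].astype(float)) > 0.0
        pos[miss[:, j], j, :] = np.nan
    return SkeletonRecording(
        timestamps=times,
        positions=pos,
        landmarks=rec.landmarks,
        missing=miss,
        nominal_rate=rec.nominal_rate,
        frame_label=rec.frame_label,
        axis_convention=rec.axis_convention,
        meta=dict(rec.meta),
    )


def resample_to(
    rec: SkeletonRecording, cfg: PreprocessConfig = PreprocessConfig()
) -> SkeletonRecording:
    """Downsample onto a uniform grid at ``cfg.target_rate_hz``.

    The grid starts at the first source timestamp and steps by exactly
    1/rate; values are linearly interpolated and missingness propagates.
    """
    if rec.n_frames < 2:
        raise DataError("need at least 2 frames to resample")
    if rec.nominal_rate < cfg.target_rate_hz:
        raise DataError("source rate below target rate")
    step = 1.0 / cfg.target_rate_hz
    n_out = int(np.floor((rec.timestamps[-1] - rec.timestamps[0]) / step)) + 1
    grid = rec.timestamps[0] + step * np.arange(n_out)
    out = sample_at(rec, grid)
    out.nominal_rate = cfg.target_rate_hz
    return out


def trim_to_overlap(
    ref_rec: SkeletonRecording, sensor_rec: SkeletonRecording
) -> tuple[SkeletonRecording, SkeletonRecording]:
    """Cut both recordings to the intersection of their time spans."""
    t0 = max(ref_rec.timestamps[0], sensor_rec.timestamps[0])
    t1 = min(ref_rec.timestamps[-1], sensor_rec.timestamps[-1])
    if t1 <= t0:
        raise DataError("recordings do not overlap in time")
    eps = 1e-9

    def cut(rec: SkeletonRecording) -> SkeletonRecording:
        keep = (rec.timestamps >= t0 - eps) & (rec.timestamps <= t1 + eps)
        out = rec.copy()
        out.timestamps = rec.timestamps[keep]
        out.positions = rec.positions[keep]
        out.missing = rec.missing[keep]
        return out

    return cut(ref_rec), cut(sensor_rec)


def pair_frames(
    ref_rec: SkeletonRecording, sensor_rec: SkeletonRecording
) -> tuple[np.ndarray, np.ndarray]:
    """Match sensor frames to the nearest reference frame.

    Returns (ref_indices, sensor_indices) for sensor frames whose nearest
    reference timestamp is within half a sensor sample period.
    """
    t_ref = ref_rec.timestamps
    t_sen = sensor_rec.timestamps
    idx = np.searchsorted(t_ref, t_sen)
    idx = np.clip(idx, 1, len(t_ref) - 1)
    left = idx - 1
    choose_left = np.abs(t_sen - t_ref[left]) <= np.abs(t_ref[idx] - t_sen)
    nearest = np.where(choose_left, left, idx)
    tol = 0.5 / sensor_rec.nominal_rate
    ok = np.abs(t_ref[nearest] - t_sen) < tol
    return nearest[ok], np.nonzero(ok)[0]
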