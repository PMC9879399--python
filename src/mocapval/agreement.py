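"""Accuracy and repeatability statistics for sensor-vs-reference
comparisons.

Signal level: per-landmark 3D RMSE, per-axis Pearson correlation (with the
poor / moderate / good / excellent bins) and per-axis zero-mean
signal-to-noise ratio in dB (good above 10 dB, bad below -10 dB).

Parameter level: descriptive statistics per system, mean difference,
Pearson r, ICC(A,1) for absolute agreement between systems, ICC(1,1) with
absolute and relative SEM for test-retest repeatability, and Bland-Altman
bias / limits of agreement with outlier flagging.

ICC estimators follow the McGraw & Wong mean-squares forms on complete
cases; negative estimates are reported as-is (flagged), not floored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skeleton import AXIS_AP, AXIS_ML, AXIS_V, DataError, SkeletonRecording

__all__ = [
    "rmse_3d",
    "pearson_axis",
    "snr_db",
    "icc_a1",
    "icc_1_1",
    "sem_abs_rel",
    "bland_altman",
    "SignalAccuracy",
    "signal_accuracy",
    "accuracy_report",
    "repeatability_report",
    "build_reports",
    "ACCURACY_COLUMNS",
    "REPEATABILITY_COLUMNS",
    "SIGNAL_COLUMNS",
]

SNR_CAP_DB = 120.0

AXES = (("ml", AXIS_ML), ("v", AXIS_V), ("ap", AXIS_AP))


def rmse_3d(ref_traj: np.ndarray, sensor_traj: np.ndarray) -> float:
    """Root mean square 3D Euclidean distance between paired trajectories [mm]."""
    a = np.asarray(ref_traj, float)
    b = np.asarray(sensor_traj, float)
    if a.shape != b.shape:
        raise DataError("trajectory length mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def classify_pearson(r: float) -> str:
    if r < 0.4:
        return "poor"
    if r < 0.7:
        return "moderate"
    if r <= 0.9:
        return "good"
    return "excellent"


def pearson_axis(ref_axis: np.ndarray, sensor_axis: np.ndarray) -> tuple[float, str]:
    """Product-moment correlation of one axis pair plus its accuracy class."""
    a = np.asarray(ref_axis, float)
    b = np.asarray(sensor_axis, float)
    if a.size < 3 or a.shape != b.shape:
        raise DataError("need >= 3 paired samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DataError("zero variance: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, classify_pearson(r)


def classify_snr(snr: float) -> str:
    if snr > 10.0:
        return "good"
    if snr < -10.0:
        return "bad"
    return "unclear"


def snr_db(ref_axis: np.ndarray, sensor_axis: np.ndarray) -> tuple[float, str]:
    """Zero-mean signal-to-noise ratio in dB.

    Both signals are mean-shifted; the noise is the sensor-minus-reference
    residual.  SNR = 10 log10(sum ref^2 / sum residual^2), capped at
    +120 dB when the residual power vanishes.
    """
    a = np.asarray(ref_axis, float)
    b = np.asarray(sensor_axis, float)
    if a.size < 3 or a.shape != b.shape:
        raise DataError("need >= 3 paired samples")
    a0 = a - a.mean()
    b0 = b - b.mean()
    p_sig = float(np.sum(a0**2))
    if p_sig == 0:
        raise DataError("reference signal has zero variance")
    p_noise = float(np.sum((b0 - a0) ** 2))
    if p_noise == 0:
        return SNR_CAP_DB, classify_snr(SNR_CAP_DB)
    snr = 10.0 * math.log10(p_sig / p_noise)
    snr = min(snr, SNR_CAP_DB)
    return snr, classify_snr(snr)


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    M = np.asarray(matrix, float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise DataError("ratings matrix must be at least 2x2")
    if not np.all(np.isfinite(M)):
        raise DataError("ratings matrix must be complete (no missing cells)")
    return M


def icc_a1(matrix: np.ndarray) -> float:
    """Two-way single-measure absolute-agreement ICC(A,1).

    Mean-squares form: (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)),
    rows = subjects, columns = systems/raters.  All-identical matrices
    return 1 by convention.  The estimate is clamped to [-1, 1].
    """
    M = _check_matrix(matrix)
    n, k = M.shape
    if np.ptp(M) == 0:
        return 1.0
    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((M - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        return 1.0
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


def icc_1_1(matrix: np.ndarray) -> float:
    """One-way random-effects single-measure ICC(1,1):
    (MSB - MSW) / (MSB + (k-1) MSW)."""
    M = _check_matrix(matrix)
    n, k = M.shape
    if np.ptp(M) == 0:
        return 1.0
    grand = M.mean()
    row_means = M.mean(axis=1)
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((M - row_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 1.0
    return float(np.clip((msb - msw) / denom, -1.0, 1.0))


def sem_abs_rel(matrix: np.ndarray, icc: float) -> tuple[float, float]:
    """Standard error of measurement: pooled SD x sqrt(1 - ICC), plus its
    percentage of the grand mean.  SEM% is NaN when the grand mean is 0."""
    M = _check_matrix(matrix)
    if not 0.0 <= icc <= 1.0:
        icc = float(np.clip(icc, 0.0, 1.0))
    sd = float(np.std(M, ddof=1))
    sem = sd * math.sqrt(1.0 - icc)
    grand = float(M.mean())
    sem_pct = math.nan if grand == 0 else sem / abs(grand) * 100.0
    return sem, sem_pct


def bland_altman(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Bland-Altman agreement: bias, 1.96-SD limits of agreement, and the
    indices of pairs whose difference falls outside the limits."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.size < 3:
        raise DataError("need >= 3 paired values")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outliers = np.nonzero((diffs < lo) | (diffs > hi))[0]
    return {
        "bias": bias,
        "loa_low": lo,
        "loa_high": hi,
        "outlier_indices": outliers.tolist(),
        "mean_values": ((a + b) / 2.0).tolist(),
        "diffs": diffs.tolist(),
    }


# ---------------------------------------------------------------------------
# signal-level report
# ---------------------------------------------------------------------------

SIGNAL_COLUMNS = (
    "landmark",
    "rmse_mm",
    "r_ml",
    "r_v",
    "r_ap",
    "r_class_ml",
    "r_class_v",
    "r_class_ap",
    "snr_ml_db",
    "snr_v_db",
    "snr_ap_db",
    "snr_class_ml",
    "snr_class_v",
    "snr_class_ap",
)


@dataclass
class SignalAccuracy:
    landmark: str
    rmse_mm: float
    pearson_r: dict[str, float]
    r_class: dict[str, str]
    snr_db: dict[str, float]
    snr_class: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "landmark": self.landmark,
            "rmse_mm": self.rmse_mm,
            "pearson_r": self.pearson_r,
            "r_class": self.r_class,
            "snr_db": self.snr_db,
            "snr_class": self.snr_class,
        }


def signal_accuracy(
    ref_rec: SkeletonRecording, sensor_rec: SkeletonRecording
) -> list[SignalAccuracy]:
    """Per-landmark signal accuracy of frame-paired recordings.

    Both recordings must already be aligned and sampled on the same
    timestamps; frames missing in either system are dropped per landmark.
    """
    if ref_rec.n_frames != sensor_rec.n_frames:
        raise DataError("recordings must be frame-paired")
    out: list[SignalAccuracy] = []
    for lm in ref_rec.landmarks:
        if lm not in sensor_rec.landmarks:
            continue
        a = ref_rec.get(lm)
        b = sensor_rec.get(lm)
        ok = ~(ref_rec.get_missing(lm) | sensor_rec.get_missing(lm))
        if ok.sum() < 3:
            continue
        a, b = a[ok], b[ok]
        rs, rc, ss, sc = {}, {}, {}, {}
        for name, axis in AXES:
            try:
                r, klass = pearson_axis(a[:, axis], b[:, axis])
            except DataError:
                r, klass = math.nan, "undefined"
            rs[name], rc[name] = r, klass
            try:
                s, sklass = snr_db(a[:, axis], b[:, axis])
            except DataError:
                s, sklass = math.nan, "undefined"
            ss[name], sc[name] = s, sklass
        out.append(SignalAccuracy(lm, rmse_3d(a, b), rs, rc, ss, sc))
    return out


def signal_accuracy_frame(accuracies: list[SignalAccuracy]) -> pd.DataFrame:
    rows = []
    for acc in accuracies:
        rows.append(
            {
                "landmark": acc.landmark,
                "rmse_mm": acc.rmse_mm,
                **{f"r_{ax}": acc.pearson_r[ax] for ax, _ in AXES},
                **{f"r_class_{ax}": acc.r_class[ax] for ax, _ in AXES},
                **{f"snr_{ax}_db": acc.snr_db[ax] for ax, _ in AXES},
                **{f"snr_class_{ax}": acc.snr_class[ax] for ax, _ in AXES},
            }
        )
    return pd.DataFrame(rows, columns=list(SIGNAL_COLUMNS))


# ---------------------------------------------------------------------------
# parameter-level reports
# ---------------------------------------------------------------------------

ACCURACY_COLUMNS = (
    "task",
    "parameter",
    "n",
    "ref_mean",
    "ref_sd",
    "sensor_mean",
    "sensor_sd",
    "mean_diff",
    "pearson_r",
    "icc_a1",
    "ba_bias",
    "ba_loa_low",
    "ba_loa_high",
    "ba_n_outliers",
)

REPEATABILITY_COLUMNS = (
    "task",
    "parameter",
    "system",
    "n",
    "k",
    "mean",
    "sd",
    "icc_1_1",
    "sem",
    "sem_pct",
)


def _first_available_rep(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per (subject, task, parameter, system): keep repetition 1, or the
    next available repetition if 1 is missing (flagged)."""
    flags: list[str] = []
    df = df.sort_values("repetition")
    keep = df.groupby(
        ["subject", "task", "parameter", "system"], as_index=False, sort=False
    ).first()
    used_later = keep[keep["repetition"] > 1]
    for row in used_later.itertuples():
        flags.append(
            f"{row.subject}/{row.task}/{row.parameter}/{row.system}: "
            f"repetition {row.repetition} used (rep 1 unavailable)"
        )
    return keep, flags


def accuracy_report(param_table: pd.DataFrame) -> tuple[pd.DataFrame, dict, list[str]]:
    """Between-system accuracy using the first available measurement per
    subject.

    ``param_table`` has columns subject, task, repetition, system,
    parameter, value, where system is REFERENCE or SENSOR.  Returns the
    accuracy table, a dict of Bland-Altman payloads keyed by
    (task, parameter), and flags.
    """
    firsts, flags = _first_available_rep(param_table.dropna(subset=["value"]))
    wide = firsts.pivot_table(
        index=["task", "parameter", "subject"],
        columns="system",
        values="value",
        aggfunc="first",
    )
    rows = []
    ba_payloads: dict[tuple[str, str], dict] = {}
    for (task, parameter), grp in wide.groupby(level=[0, 1]):
        grp = grp.dropna()
        if grp.empty or not {"REFERENCE", "SENSOR"}.issubset(grp.columns):
            continue
        ref = grp["REFERENCE"].to_numpy(float)
        sen = grp["SENSOR"].to_numpy(float)
        n = ref.size
        row = {
            "task": task,
            "parameter": parameter,
            "n": n,
            "ref_mean": ref.mean(),
            "ref_sd": ref.std(ddof=1) if n > 1 else 0.0,
            "sensor_mean": sen.mean(),
            "sensor_sd": sen.std(ddof=1) if n > 1 else 0.0,
            "mean_diff": (sen - ref).mean(),
        }
        try:
            row["pearson_r"], _ = pearson_axis(ref, sen)
        except DataError:
            row["pearson_r"] = math.nan
        try:
            row["icc_a1"] = icc_a1(np.column_stack([ref, sen]))
        except DataError:
            row["icc_a1"] = math.nan
        try:
            ba = bland_altman(sen, ref)
            ba_payloads[(task, parameter)] = ba
            row.update(
                ba_bias=ba["bias"],
                ba_loa_low=ba["loa_low"],
                ba_loa_high=ba["loa_high"],
                ba_n_outliers=len(ba["outlier_indices"]),
            )
        except DataError:
            row.update(
                ba_bias=math.nan,
                ba_loa_low=math.nan,
                ba_loa_high=math.nan,
                ba_n_outliers=0,
            )
        if row.get("icc_a1", 0) is not math.nan and row.get("icc_a1", 0) < 0:
            flags.append(f"{task}/{parameter}: negative ICC(A,1)")
        rows.append(row)
    return (
        pd.DataFrame(rows, columns=list(ACCURACY_COLUMNS)),
        ba_payloads,
        flags,
    )


def repeatability_report(param_table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Within-system repeatability over repeated measurements: ICC(1,1)
    plus absolute and relative SEM, per parameter and system.

    Subjects with incomplete repetition sets are reduced to the common
    complete-case repetitions; subjects lacking them are dropped (count
    reported via the ``n`` column).
    """
    flags: list[str] = []
    rows = []
    df = param_table.dropna(subset=["value"])
    for (task, parameter, system), grp in df.groupby(["task", "parameter", "system"]):
        mat = grp.pivot_table(
            index="subject", columns="repetition", values="value", aggfunc="first"
        )
        mat = mat.dropna(axis=0)
        if mat.shape[0] < 2 or mat.shape[1] < 2:
            flags.append(f"{task}/{parameter}/{system}: too few complete cases")
            continue
        M = mat.to_numpy(float)
        icc = icc_1_1(M)
        sem, sem_pct = sem_abs_rel(M, max(icc, 0.0))
        if icc < 0:
            flags.append(f"{task}/{parameter}/{system}: negative ICC(1,1)")
        rows.append(
            {
                "task": task,
                "parameter": parameter,
                "system": system,
                "n": M.shape[0],
                "k": M.shape[1],
                "mean": M.mean(),
                "sd": float(np.std(M, ddof=1)),
                "icc_1_1": icc,
                "sem": sem,
                "sem_pct": sem_pct,
            }
        )
    return pd.DataFrame(rows, columns=list(REPEATABILITY_COLUMNS)), flags


@dataclass
class AgreementReport:
    """Machine twin of the published accuracy/repeatability tables."""

    accuracy: pd.DataFrame
    repeatability: pd.DataFrame
    bland_altman: dict[tuple[str, str], dict]
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy.to_dict(orient="records"),
            "repeatability": self.repeatability.to_dict(orient="records"),
            "bland_altman": {
                f"{t}/{p}": ba for (t, p), ba in self.bland_altman.items()
            },
            "flags": list(self.flags),
        }


def build_reports(param_table: pd.DataFrame) -> AgreementReport:
    """Build the accuracy (first-repetition, between-system) and
    repeatability (all repetitions, within-system) reports from a long
    parameter table with columns subject, task, repetition, system,
    parameter, value."""
    required = {"subject", "task", "repetition", "system", "parameter", "value"}
    if not required.issubset(param_table.columns):
        raise DataError(f"parameter table needs columns {sorted(required)}")
    acc, ba, flags_a = accuracy_report(param_table)
    rep, flags_r = repeatability_report(param_table)
    return AgreementReport(acc, rep, ba, flags_a + flags_r)
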