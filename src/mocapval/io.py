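"""Delimited-text I/O for landmark tables, manifests and result bundles.

The on-disk dialect is a flat UTF-8 delimited table with header
``time,<lm>_x,<lm>_y,<lm>_z,...`` — time in seconds, positions in mm.
Missing samples are serialized as blank cells and come back as entries of
the missing mask.  A manifest is a delimited table with columns
``subject,task,repetition,system,path`` pointing at one landmark table per
recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .skeleton import (
    CANONICAL_AXES,
    DataError,
    FormatError,
    SkeletonRecording,
    System,
    Task,
    TaskRecording,
)

__all__ = [
    "TableDialect",
    "read_landmark_table",
    "write_landmark_table",
    "read_manifest",
    "write_manifest",
    "ManifestEntry",
]

_SUFFIXES = ("_x", "_y", "_z")


@dataclass(frozen=True)
class TableDialect:
    """Fixes delimiter and units of a landmark table."""

    delimiter: str = ","
    time_column: str = "time"
    position_units: str = "mm"  # "mm" or "m"

    @property
    def scale_to_mm(self) -> float:
        if self.position_units == "mm":
            return 1.0
        if self.position_units == "m":
            return 1000.0
        raise FormatError(f"unknown position units {self.position_units!r}")


def _landmarks_from_header(columns: list[str], dialect: TableDialect) -> list[str]:
    if not columns or columns[0] != dialect.time_column:
        raise FormatError(
            f"first column must be {dialect.time_column!r}, got {columns[:1]}"
        )
    body = columns[1:]
    if len(body) % 3 != 0:
        raise FormatError("landmark columns must come in x/y/z triples")
    landmarks: list[str] = []
    for i in range(0, len(body), 3):
        triple = body[i : i + 3]
        names = {c.rsplit("_", 1)[0] for c in triple}
        suffixes = tuple(c.rsplit("_", 1)[1] for c in triple)
        if len(names) != 1 or suffixes != ("x", "y", "z"):
            raise FormatError(f"malformed column triple {triple}")
        landmarks.append(triple[0][: -len("_x")])
    if len(set(landmarks)) != len(landmarks):
        raise FormatError("duplicated landmark columns")
    return landmarks


def read_landmark_table(
    path: str | Path,
    dialect: TableDialect = TableDialect(),
    nominal_rate: float | None = None,
    frame_label: str = "file",
) -> SkeletonRecording:
    """Read a delimited landmark table into a :class:`SkeletonRecording`.

    Blank or unparsable position cells become missing-mask entries.  A frame
    is flagged missing for a landmark if any of its three coordinate cells
    is missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter)
    landmarks = _landmarks_from_header(list(df.columns), dialect)
    t = pd.to_numeric(df[dialect.time_column], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(t)):
        raise DataError(f"{path}: unparsable timestamps")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise DataError(f"{path}: timestamps not strictly increasing")
    n = len(df)
    pos = np.empty((n, len(landmarks), 3))
    for j, lm in enumerate(landmarks):
        for a, suf in enumerate(_SUFFIXES):
            col = pd.to_numeric(df[lm + suf], errors="coerce")
            pos[:, j, a] = col.to_numpy(float)
    pos *= dialect.scale_to_mm
    missing = ~np.isfinite(pos).all(axis=2)
    if nominal_rate is None:
        nominal_rate = 1.0 / float(np.median(np.diff(t))) if n > 1 else 30.0
    return SkeletonRecording(
        timestamps=t,
        positions=pos,
        landmarks=tuple(landmarks),
        missing=missing,
        nominal_rate=nominal_rate,
        frame_label=frame_label,
        axis_convention=CANONICAL_AXES,
    )


def write_landmark_table(
    rec: SkeletonRecording,
    path: str | Path,
    dialect: TableDialect = TableDialect(),
    float_format: str = "%.9f",
) -> None:
    """Serialize a recording as a delimited table re-readable by
    :func:`read_landmark_table`.  Missing samples are written as blanks."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {dialect.time_column: rec.timestamps}
    scale = dialect.scale_to_mm
    for j, lm in enumerate(rec.landmarks):
        for a, suf in enumerate(_SUFFIXES):
            vals = rec.positions[:, j, a] / scale
            vals = np.where(rec.missing[:, j], np.nan, vals)
            cols[lm + suf] = vals
    df = pd.DataFrame(cols)
    df.to_csv(path, sep=dialect.delimiter, index=False, float_format=float_format)


@dataclass(frozen=True)
class ManifestEntry:
    subject: str
    task: str
    repetition: int
    system: str
    path: str


def read_manifest(path: str | Path, dialect: TableDialect = TableDialect()) -> list[ManifestEntry]:
    df = pd.read_csv(path, sep=dialect.delimiter)
    required = {"subject", "task", "repetition", "system", "path"}
    if not required.issubset(df.columns):
        raise FormatError(f"manifest must have columns {sorted(required)}")
    return [
        ManifestEntry(
            subject=str(r.subject),
            task=str(r.task),
            repetition=int(r.repetition),
            system=str(r.system),
            path=str(r.path),
        )
        for r in df.itertuples()
    ]


def write_manifest(entries: list[ManifestEntry], path: str | Path) -> None:
    pd.DataFrame([asdict(e) for e in entries]).to_csv(path, index=False)


def load_task_recording(
    entry: ManifestEntry,
    base_dir: str | Path = ".",
    dialect: TableDialect = TableDialect(),
) -> TaskRecording:
    rate = 178.0 if entry.system == System.REFERENCE.value else 30.0
    rec = read_landmark_table(Path(base_dir) / entry.path, dialect, nominal_rate=rate)
    return TaskRecording(
        task=Task(entry.task),
        subject_id=entry.subject,
        repetition_index=entry.repetition,
        system=System(entry.system),
        recording=rec,
    )


def dump_json(obj, path: str | Path) -> None:
    """Write any result object with ``to_dict``/dataclass support as JSON."""

    def default(o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
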