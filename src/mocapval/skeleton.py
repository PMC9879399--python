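"""Domain types for landmark time series.

The package works on skeletons described by a fixed vocabulary of named
anatomical landmarks.  The 21-landmark ``COMMON`` set is the intersection
tracked both by depth-camera body-tracking SDKs and by marker-based
reference systems once their raw marker/joint sets have been mapped onto a
shared vocabulary; all clinical parameter extraction operates on this set.

Coordinates follow the convention x = medio-lateral (+ right),
y = vertical (+ up), z = anterior-posterior, in millimetres.  Subjects face
the sensor along decreasing z, i.e. walking toward the sensor decreases the
AP coordinate of the spine base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AXIS_ML",
    "AXIS_V",
    "AXIS_AP",
    "CANONICAL_AXES",
    "COMMON_LANDMARKS",
    "COMMON_SET",
    "AZURE_32_LANDMARKS",
    "DEFAULT_AZURE_TO_COMMON",
    "LANDMARK_CLASS",
    "Task",
    "System",
    "LandmarkSet",
    "SkeletonRecording",
    "TaskRecording",
    "LandmarkMapping",
    "map_landmarks",
    "FormatError",
    "DataError",
]

AXIS_ML, AXIS_V, AXIS_AP = 0, 1, 2
CANONICAL_AXES = "x=ML,y=V,z=AP"

#: The 21 landmarks shared by the markerless and the reference system.
COMMON_LANDMARKS: tuple[str, ...] = (
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
    "knee_l",
    "knee_r",
    "ankle_l",
    "ankle_r",
    "foot_l",
    "foot_r",
)

#: Body-region class per common landmark, used for noise models and
#: registration subsets (trunk landmarks are the least noisy).
LANDMARK_CLASS: dict[str, str] = {
    "head": "trunk",
    "neck": "trunk",
    "spine_shoulder": "trunk",
    "spine_mid": "trunk",
    "spine_base": "trunk",
    "shoulder_l": "trunk",
    "shoulder_r": "trunk",
    "hip_l": "trunk",
    "hip_r": "trunk",
    "elbow_l": "arms",
    "elbow_r": "arms",
    "wrist_l": "arms",
    "wrist_r": "arms",
    "hand_l": "arms",
    "hand_r": "arms",
    "knee_l": "knees",
    "knee_r": "knees",
    "ankle_l": "feet",
    "ankle_r": "feet",
    "foot_l": "feet",
    "foot_r": "feet",
}

#: Trunk landmarks used by default for rigid registration.
TRUNK_LANDMARKS: tuple[str, ...] = (
    "spine_base",
    "spine_mid",
    "spine_shoulder",
    "hip_l",
    "hip_r",
)

#: The 32-joint vocabulary of the current-generation body tracking SDK.
AZURE_32_LANDMARKS: tuple[str, ...] = (
    "pelvis",
    "spine_navel",
    "spine_chest",
    "neck",
    "clavicle_l",
    "shoulder_l",
    "elbow_l",
    "wrist_l",
    "hand_l",
    "handtip_l",
    "thumb_l",
    "clavicle_r",
    "shoulder_r",
    "elbow_r",
    "wrist_r",
    "hand_r",
    "handtip_r",
    "thumb_r",
    "hip_l",
    "knee_l",
    "ankle_l",
    "foot_l",
    "hip_r",
    "knee_r",
    "ankle_r",
    "foot_r",
    "head",
    "nose",
    "eye_l",
    "ear_l",
    "eye_r",
    "ear_r",
)

#: Default anatomical correspondence from the 32-joint SDK set onto the
#: common vocabulary (pelvis -> spine base, chest -> spine shoulder, ...).
#: Shipped as editable data so site-specific mappings can replace it.
DEFAULT_AZURE_TO_COMMON: dict[str, tuple[str, ...]] = {
    "head": ("head",),
    "neck": ("neck",),
    "spine_shoulder": ("spine_chest",),
    "shoulder_l": ("shoulder_l",),
    "shoulder_r": ("shoulder_r",),
    "elbow_l": ("elbow_l",),
    "elbow_r": ("elbow_r",),
    "wrist_l": ("wrist_l",),
    "wrist_r": ("wrist_r",),
    "hand_l": ("hand_l",),
    "hand_r": ("hand_r",),
    "spine_mid": ("spine_navel",),
    "spine_base": ("pelvis",),
    "hip_l": ("hip_l",),
    "hip_r": ("hip_r",),
    "knee_l": ("knee_l",),
    "knee_r": ("knee_r",),
    "ankle_l": ("ankle_l",),
    "ankle_r": ("ankle_r",),
    "foot_l": ("foot_l",),
    "foot_r": ("foot_r",),
}


class FormatError(ValueError):
    """A landmark table or config file violates the expected layout."""


class DataError(ValueError):
    """Parsed data violates a semantic invariant (e.g. non-monotone time)."""


class Task(str, Enum):
    """The four clinical motor tasks."""

    POCO = "POCO"  # quiet stance, postural control
    SAS = "SAS"  # stand up and sit down
    SIP = "SIP"  # stepping in place
    SCSW = "SCSW"  # short comfortable-speed walk


class System(str, Enum):
    REFERENCE = "REFERENCE"
    SENSOR = "SENSOR"


@dataclass(frozen=True)
class LandmarkSet:
    """A named, ordered vocabulary of landmark identifiers."""

    name: str
    landmarks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.landmarks)) != len(self.landmarks):
            raise FormatError(f"duplicate landmark in set {self.name!r}")

    def __contains__(self, landmark: str) -> bool:
        return landmark in self.landmarks

    def index(self, landmark: str) -> int:
        return self.landmarks.index(landmark)

    def __len__(self) -> int:
        return len(self.landmarks)


COMMON_SET = LandmarkSet("common21", COMMON_LANDMARKS)
AZURE_SET = LandmarkSet("azure32", AZURE_32_LANDMARKS)


@dataclass
class SkeletonRecording:
    """Timestamped 3D positions for a landmark set, with a missing mask.

    Parameters
    ----------
    timestamps
        Strictly increasing sample times in seconds, shape ``(n,)``.
    positions
        Positions in millimetres, shape ``(n, n_landmarks, 3)``.  Entries
        flagged missing may hold NaN.
    landmarks
        Ordered landmark names matching axis 1 of ``positions``.
    missing
        Boolean mask, shape ``(n, n_landmarks)``; True marks a dropped /
        unparsable sample.
    nominal_rate
        Nominal sampling rate in Hz.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    landmarks: tuple[str, ...]
    missing: np.ndarray | None = None
    nominal_rate: float = 30.0
    frame_label: str = "unknown"
    axis_convention: str = CANONICAL_AXES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.landmarks = tuple(self.landmarks)
        n = self.timestamps.shape[0]
        if self.positions.shape != (n, len(self.landmarks), 3):
            raise DataError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} frames x {len(self.landmarks)} landmarks x 3"
            )
        if self.missing is None:
            self.missing = np.zeros((n, len(self.landmarks)), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, len(self.landmarks)):
                raise DataError("missing mask shape mismatch")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise DataError("timestamps must be strictly increasing")
        if self.nominal_rate <= 0:
            raise DataError("nominal_rate must be positive")

    # -- basic introspection -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def index(self, landmark: str) -> int:
        try:
            return self.landmarks.index(landmark)
        except ValueError:
            raise KeyError(f"landmark {landmark!r} not in recording") from None

    def get(self, landmark: str) -> np.ndarray:
        """Positions of one landmark, shape ``(n, 3)``."""
        return self.positions[:, self.index(landmark), :]

    def get_missing(self, landmark: str) -> np.ndarray:
        return self.missing[:, self.index(landmark)]

    def copy(self) -> "SkeletonRecording":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            positions=self.positions.copy(),
            missing=self.missing.copy(),
            meta=dict(self.meta),
        )

    def validate(self) -> None:
        """Raise :class:`DataError` on any violated structural invariant."""
        present = ~self.missing
        if not np.all(np.isfinite(self.positions[present])):
            raise DataError("non-finite position outside missing mask")


@dataclass
class TaskRecording:
    """A skeleton recording tagged with its study context."""

    task: Task
    subject_id: str
    repetition_index: int
    system: System
    recording: SkeletonRecording

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.system = System(self.system)
        if not 1 <= int(self.repetition_index) <= 5:
            raise DataError("repetition_index must be in 1..5")


@dataclass(frozen=True)
class LandmarkMapping:
    """Rules building a target landmark set out of a source set.

    Each target landmark is either copied from a single source landmark or
    computed as the unweighted mean of two or more source landmarks (the
    usual trick to place e.g. a spine-base landmark between paired pelvis
    markers).
    """

    source_set: LandmarkSet
    target_set: LandmarkSet
    rules: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for target in self.target_set.landmarks:
            if target not in self.rules:
                raise FormatError(f"no mapping rule for target {target!r}")
        for target, sources in self.rules.items():
            if target not in self.target_set:
                raise FormatError(f"rule target {target!r} not in target set")
            if len(sources) == 0:
                raise FormatError(f"empty rule for {target!r}")
            for src in sources:
                if src not in self.source_set:
                    raise FormatError(
                        f"rule for {target!r} references unknown source {src!r}"
                    )

    @classmethod
    def identity(cls, landmark_set: LandmarkSet) -> "LandmarkMapping":
        return cls(
            landmark_set,
            landmark_set,
            {lm: (lm,) for lm in landmark_set.landmarks},
        )


def azure_to_common_mapping(
    rules: Mapping[str, Sequence[str]] | None = None,
) -> LandmarkMapping:
    """The default (or a user-supplied) 32-joint -> common-21 mapping."""
    raw = rules if rules is not None else DEFAULT_AZURE_TO_COMMON
    return LandmarkMapping(
        AZURE_SET, COMMON_SET, {k: tuple(v) for k, v in raw.items()}
    )


def map_landmarks(rec: SkeletonRecording, mapping: LandmarkMapping) -> SkeletonRecording:
    """Project a recording onto the mapping's target landmark set.

    Mean rules average only frames where every source landmark is present;
    frames with any missing source are flagged missing in the output.
    """
    if tuple(rec.landmarks) != mapping.source_set.landmarks:
        raise FormatError(
            "recording landmarks do not match the mapping's source set"
        )
    n = rec.n_frames
    targets = mapping.target_set.landmarks
    out_pos = np.empty((n, len(targets), 3))
    out_missing = np.zeros((n, len(targets)), dtype=bool)
    for j, target in enumerate(targets):
        sources = mapping.rules[target]
        idx = [rec.index(s) for s in sources]
        miss = rec.missing[:, idx].any(axis=1)
        out_missing[:, j] = miss
        out_pos[:, j, :] = rec.positions[:, idx, :].mean(axis=1)
        out_pos[miss, j, :] = np.nan
    return SkeletonRecording(
        timestamps=rec.timestamps.copy(),
        positions=out_pos,
        landmarks=targets,
        missing=out_missing,
        nominal_rate=rec.nominal_rate,
        frame_label=rec.frame_label,
        axis_convention=rec.axis_convention,
        meta=dict(rec.meta),
    )
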