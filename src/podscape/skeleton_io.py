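"""Data model and I/O for 3-D skeleton trajectories, movement-label streams
and arena/session metadata.

The canonical kinematic input is a ``SkeletonTrajectory``: per-frame x, y, z
coordinates (mm) of 16 named body parts recorded at a fixed frame rate
(30 frames/s by default).  Alongside it runs a ``MovementLabelStream``, a
per-frame class label over a 40-class movement vocabulary produced by an
upstream movement-segmentation tool.  Arena geometry (circular open field or
square novel-object box with up to two objects) is described by ``ArenaSpec``
and ``ObjectSpec``; a ``SessionRecord`` bundles one recording session.

File dialects are deliberately simple and text-based:

* trajectory CSV — header row ``frame,<keypoint>_x,<keypoint>_y,<keypoint>_z``
  for the 16 canonical keypoints, coordinates in mm, frame indices 1-based;
* label CSV — either dense (``frame,label``) or a segment table
  (``start,end,label``) with 1-based inclusive segments;
* session metadata — a JSON sidecar carrying arena geometry, group labels
  and any generator ground truth.

Foreign trajectory headers can be adapted with a ``column_map`` that maps a
canonical keypoint name to the prefix used in the file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical keypoint names, in canonical order.
KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_ear",
    "right_ear",
    "neck",
    "left_front_limb",
    "right_front_limb",
    "left_hind_limb",
    "right_hind_limb",
    "left_front_claw",
    "right_front_claw",
    "left_hind_claw",
    "right_hind_claw",
    "back",
    "root_tail",
    "middle_tail",
    "tail_tip",
)

N_KEYPOINTS = len(KEYPOINT_NAMES)

#: Size of the movement vocabulary (classes M1..M40).
VOCABULARY_SIZE = 40

DEFAULT_FRAME_RATE = 30.0

AXES = ("x", "y", "z")


class SkeletonFormatError(ValueError):
    """A trajectory or label file does not conform to the expected dialect."""


class SkeletonValidationError(ValueError):
    """In-memory data violates a structural invariant."""


def keypoint_index(name: str) -> int:
    """Index of a canonical keypoint name within the keypoint axis."""
    try:
        return KEYPOINT_NAMES.index(name)
    except ValueError:
        raise KeyError(f"unknown keypoint {name!r}") from None


@dataclass(frozen=True)
class SkeletonTrajectory:
    """T x 16 x 3 array of keypoint coordinates in mm at a fixed frame rate."""

    frames: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    keypoint_names: tuple[str, ...] = KEYPOINT_NAMES

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "keypoint_names", tuple(self.keypoint_names))
        if frames.ndim != 3 or frames.shape[1:] != (N_KEYPOINTS, 3):
            raise SkeletonValidationError(
                f"expected a T x {N_KEYPOINTS} x 3 array, got shape {frames.shape}"
            )
        if frames.shape[0] < 2:
            raise SkeletonValidationError("a trajectory needs at least 2 frames")
        if self.keypoint_names != KEYPOINT_NAMES:
            raise SkeletonValidationError(
                "keypoints must be the 16 canonical names in canonical order"
            )
        if self.frame_rate <= 0:
            raise SkeletonValidationError("frame_rate must be positive")
        if not np.isfinite(frames).all():
            bad = np.argwhere(~np.isfinite(frames).all(axis=(1, 2)))[0, 0]
            raise SkeletonValidationError(
                f"non-finite coordinate at frame {bad + 1}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        """Session duration in seconds."""
        return self.n_frames / self.frame_rate

    def keypoint(self, name: str) -> np.ndarray:
        """(T, 3) coordinate series of one keypoint."""
        return self.frames[:, keypoint_index(name), :]


@dataclass(frozen=True)
class MovementLabelStream:
    """Per-frame movement-class labels over the 40-class vocabulary."""

    labels: np.ndarray
    vocabulary_size: int = VOCABULARY_SIZE

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1 or labels.size == 0:
            raise SkeletonValidationError("labels must be a non-empty 1-D sequence")
        if labels.min() < 1 or labels.max() > self.vocabulary_size:
            bad = labels[(labels < 1) | (labels > self.vocabulary_size)][0]
            raise SkeletonValidationError(
                f"label {bad} outside vocabulary 1..{self.vocabulary_size}"
            )

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def to_segments(self) -> pd.DataFrame:
        """Run-length encode into a (start, end, label) table, 1-based inclusive."""
        labels = self.labels
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [labels.size]))
        return pd.DataFrame(
            {"start": starts + 1, "end": ends, "label": labels[starts]}
        )

    @classmethod
    def from_segments(
        cls,
        segments: pd.DataFrame,
        n_frames: int,
        vocabulary_size: int = VOCABULARY_SIZE,
    ) -> "MovementLabelStream":
        """Expand a 1-based inclusive segment table into a dense stream.

        Segments must tile ``1..n_frames`` exactly: overlaps and gaps raise.
        """
        seg = segments.sort_values("start").reset_index(drop=True)
        labels = np.zeros(n_frames, dtype=int)
        cursor = 1
        for row in seg.itertuples(index=False):
            start, end, label = int(row.start), int(row.end), int(row.label)
            if start < cursor:
                raise SkeletonFormatError(
                    f"overlapping segments near frame {start}: "
                    f"segment ({start}, {end}, {label}) starts before frame {cursor}"
                )
            if start > cursor:
                raise SkeletonFormatError(
                    f"gap in segment coverage: frames {cursor}..{start - 1} unlabelled"
                )
            if end > n_frames:
                raise SkeletonFormatError(
                    f"segment ({start}, {end}, {label}) extends past frame {n_frames}"
                )
            if end < start:
                raise SkeletonFormatError(f"segment ({start}, {end}, {label}) has end < start")
            labels[start - 1 : end] = label
            cursor = end + 1
        if cursor != n_frames + 1:
            raise SkeletonFormatError(
                f"segments end at frame {cursor - 1}, expected {n_frames}"
            )
        return cls(labels=labels, vocabulary_size=vocabulary_size)


@dataclass(frozen=True)
class ObjectSpec:
    """One physical object placed in the arena."""

    centre: tuple[float, float]
    footprint_radius: float
    top_height: float
    role: str  # "familiar" | "novel"

    def __post_init__(self) -> None:
        if self.footprint_radius <= 0:
            raise SkeletonValidationError("footprint_radius must be positive")
        if self.top_height <= 0:
            raise SkeletonValidationError("top_height must be positive")
        if self.role not in ("familiar", "novel"):
            raise SkeletonValidationError(f"unknown object role {self.role!r}")
        object.__setattr__(self, "centre", (float(self.centre[0]), float(self.centre[1])))


@dataclass(frozen=True)
class ArenaSpec:
    """Arena geometry: circular open field or square box, with 0-2 objects.

    ``size`` is the diameter (circle) or side length (square), in mm; the
    coordinate origin is the arena centre.
    """

    shape: str  # "circle" | "square"
    size: float
    height: float = 500.0
    objects: tuple[ObjectSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square"):
            raise SkeletonValidationError(f"unknown arena shape {self.shape!r}")
        if self.size <= 0:
            raise SkeletonValidationError("arena size must be positive")
        if len(self.objects) > 2:
            raise SkeletonValidationError("at most 2 objects supported")
        object.__setattr__(self, "objects", tuple(self.objects))

    @property
    def half_extent(self) -> float:
        return self.size / 2.0

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of 2-D points inside the arena footprint."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        if self.shape == "circle":
            return np.hypot(xy[:, 0], xy[:, 1]) <= self.half_extent + 1e-9
        return (np.abs(xy) <= self.half_extent + 1e-9).all(axis=1)

    def object_by_role(self, role: str) -> ObjectSpec:
        for obj in self.objects:
            if obj.role == role:
                return obj
        raise KeyError(f"arena has no object with role {role!r}")


def open_field_arena(diameter: float = 500.0, height: float = 500.0) -> ArenaSpec:
    """The circular open field (50 cm diameter by default)."""
    return ArenaSpec(shape="circle", size=diameter, height=height)


def novel_object_arena(
    side: float = 400.0,
    height: float = 500.0,
    object_distance: float = 200.0,
    footprint_radius: float = 25.0,
    top_height: float = 60.0,
) -> ArenaSpec:
    """The square novel-object box (40 x 40 cm) with two objects.

    Objects sit on opposite sides of the box, ``object_distance`` mm apart,
    centred on the x axis.
    """
    half = object_distance / 2.0
    objects = (
        ObjectSpec(centre=(-half, 0.0), footprint_radius=footprint_radius,
                   top_height=top_height, role="familiar"),
        ObjectSpec(centre=(half, 0.0), footprint_radius=footprint_radius,
                   top_height=top_height, role="novel"),
    )
    return ArenaSpec(shape="square", size=side, height=height, objects=objects)


VALID_GROUPS = ("control", "model", "dex")
VALID_TIMEPOINTS = (6, 30, 54, 78)
VALID_PARADIGMS = ("OFT", "NOR_train", "NOR_test")


@dataclass
class SessionRecord:
    """One recorded (or simulated) behavioural session."""

    animal_id: str
    group: str
    paradigm: str
    trajectory: SkeletonTrajectory | None = None
    labels: MovementLabelStream | None = None
    arena: ArenaSpec | None = None
    timepoint_h: int | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise SkeletonValidationError(f"unknown group {self.group!r}")
        if self.paradigm not in VALID_PARADIGMS:
            raise SkeletonValidationError(f"unknown paradigm {self.paradigm!r}")
        if self.timepoint_h is not None and self.timepoint_h not in VALID_TIMEPOINTS:
            raise SkeletonValidationError(
                f"timepoint_h must be one of {VALID_TIMEPOINTS}, got {self.timepoint_h}"
            )
        if self.paradigm.startswith("NOR"):
            if self.arena is None or not self.arena.objects:
                raise SkeletonValidationError(
                    "NOR paradigms require an arena with objects"
                )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def write_trajectory(traj: SkeletonTrajectory, path: str | Path) -> Path:
    """Write a trajectory to the canonical CSV dialect; returns the path."""
    path = Path(path)
    columns: dict[str, np.ndarray] = {
        "frame": np.arange(1, traj.n_frames + 1)
    }
    for k, name in enumerate(traj.keypoint_names):
        for a, axis in enumerate(AXES):
            columns[f"{name}_{axis}"] = traj.frames[:, k, a]
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.6f")
    return path


def read_trajectory(
    path: str | Path,
    frame_rate: float = DEFAULT_FRAME_RATE,
    column_map: Mapping[str, str] | None = None,
) -> SkeletonTrajectory:
    """Read a trajectory CSV, canonicalizing keypoint order.

    ``column_map`` maps canonical keypoint names to the column-name prefix
    used in a foreign file (e.g. ``{"root_tail": "tailbase"}``).
    """
    table = pd.read_csv(path)
    column_map = dict(column_map or {})
    blocks = []
    for name in KEYPOINT_NAMES:
        prefix = column_map.get(name, name)
        cols = [f"{prefix}_{axis}" for axis in AXES]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise SkeletonFormatError(
                f"missing coordinate column(s) for keypoint '{name}': "
                + ", ".join(missing)
            )
        blocks.append(table[cols].to_numpy(dtype=float))
    frames = np.stack(blocks, axis=1)  # T x 16 x 3
    if not np.isfinite(frames).all():
        bad = np.argwhere(~np.isfinite(frames).all(axis=(1, 2)))[0, 0]
        raise SkeletonValidationError(f"non-finite coordinate at frame {bad + 1}")
    return SkeletonTrajectory(frames=frames, frame_rate=frame_rate)


def write_labels(
    stream: MovementLabelStream, path: str | Path, style: str = "segments"
) -> Path:
    """Write a label stream as a dense (``frame,label``) or segment CSV."""
    path = Path(path)
    if style == "dense":
        pd.DataFrame(
            {"frame": np.arange(1, stream.n_frames + 1), "label": stream.labels}
        ).to_csv(path, index=False)
    elif style == "segments":
        stream.to_segments().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown label style {style!r}")
    return path


def read_labels(path: str | Path, n_frames: int) -> MovementLabelStream:
    """Read a label CSV (dense or segment form) into a dense stream."""
    table = pd.read_csv(path)
    cols = set(table.columns)
    if {"start", "end", "label"} <= cols:
        return MovementLabelStream.from_segments(table, n_frames=n_frames)
    if {"frame", "label"} <= cols:
        table = table.sort_values("frame")
        frames = table["frame"].to_numpy(dtype=int)
        if frames.size != n_frames or not np.array_equal(
            frames, np.arange(1, n_frames + 1)
        ):
            raise SkeletonFormatError(
                f"dense label file must cover frames 1..{n_frames} exactly"
            )
        labels = table["label"].to_numpy(dtype=int)
        if labels.min() < 1 or labels.max() > VOCABULARY_SIZE:
            raise SkeletonValidationError(
                f"label outside vocabulary 1..{VOCABULARY_SIZE}"
            )
        return MovementLabelStream(labels=labels)
    raise SkeletonFormatError(
        "label file must have columns (frame,label) or (start,end,label)"
    )


def _arena_to_dict(arena: ArenaSpec) -> dict:
    return {
        "shape": arena.shape,
        "size": arena.size,
        "height": arena.height,
        "objects": [
            {
                "centre": list(o.centre),
                "footprint_radius": o.footprint_radius,
                "top_height": o.top_height,
                "role": o.role,
            }
            for o in arena.objects
        ],
    }


def _arena_from_dict(data: dict) -> ArenaSpec:
    objects = tuple(
        ObjectSpec(
            centre=tuple(o["centre"]),
            footprint_radius=o["footprint_radius"],
            top_height=o["top_height"],
            role=o["role"],
        )
        for o in data.get("objects", [])
    )
    return ArenaSpec(
        shape=data["shape"], size=data["size"],
        height=data.get("height", 500.0), objects=objects,
    )


def write_session_meta(session: SessionRecord, path: str | Path) -> Path:
    """Write the session metadata sidecar (JSON)."""
    path = Path(path)
    payload = {
        "animal_id": session.animal_id,
        "group": session.group,
        "paradigm": session.paradigm,
        "timepoint_h": session.timepoint_h,
        "arena": _arena_to_dict(session.arena) if session.arena else None,
        "ground_truth": session.ground_truth,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_session_meta(path: str | Path) -> SessionRecord:
    """Read a metadata sidecar back into a (data-less) ``SessionRecord``."""
    data = json.loads(Path(path).read_text())
    arena = _arena_from_dict(data["arena"]) if data.get("arena") else None
    return SessionRecord(
        animal_id=data["animal_id"],
        group=data["group"],
        paradigm=data["paradigm"],
        arena=arena,
        timepoint_h=data.get("timepoint_h"),
        ground_truth=data.get("ground_truth", {}),
    )
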