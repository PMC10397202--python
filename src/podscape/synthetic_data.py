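"""Synthetic behavioural sessions with known ground truth.

Three generators emulate the inputs the analysis pipeline consumes:

* ``generate_labels`` — bout-structured movement-label streams whose
  long-run class fractions match a ``GroupProfile``.  Bouts follow a
  semi-Markov scheme: a class is entered with probability proportional to
  its target fraction divided by its mean bout length, and the bout
  duration is geometric, so empirical fractions converge to the profile as
  the stream grows.
* ``generate_skeleton`` — smooth reflecting-random-walk kinematics inside
  an arena, with a fixed body plan rotated by the heading, so that the
  location of the back-speed distribution scales with the profile's
  ``speed_scale`` and torso heights track ``height_scale``.
* ``generate_investigation_session`` — sessions realizing a scheduled list
  of object-investigation bouts (deep or shallow), constructed so the
  geometric investigation rules recover the schedule exactly.

All generators are pure functions of their parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .skeleton_io import (
    ArenaSpec,
    KEYPOINT_NAMES,
    MovementLabelStream,
    SkeletonTrajectory,
    SkeletonValidationError,
    VOCABULARY_SIZE,
    DEFAULT_FRAME_RATE,
)

# ---------------------------------------------------------------------------
# group profiles over the 40-class movement vocabulary
# ---------------------------------------------------------------------------

#: Movement classes elevated in delirium-like (POD) animals.
POD_UP_CLASSES: tuple[int, ...] = (4, 8, 9, 10, 22, 34, 35, 37)
#: Movement classes reduced in delirium-like (POD) animals.
POD_DOWN_CLASSES: tuple[int, ...] = (3, 16, 25, 36, 38, 40)
#: The 14 discriminative classes, ascending.
DISCRIMINATIVE_CLASSES: tuple[int, ...] = tuple(
    sorted(POD_UP_CLASSES + POD_DOWN_CLASSES)
)

#: Default mean bout duration, frames (0.3 s at 30 frames/s).
DEFAULT_MEAN_BOUT_FRAMES = 9.0
#: Default session length, frames (10 min at 30 frames/s).
DEFAULT_SESSION_FRAMES = 18_000


@dataclass(frozen=True)
class GroupProfile:
    """Expected movement-class composition of one animal group."""

    fraction_means: np.ndarray
    mean_bout_frames: float = DEFAULT_MEAN_BOUT_FRAMES
    label: str = "control-like"

    def __post_init__(self) -> None:
        fractions = np.asarray(self.fraction_means, dtype=float)
        object.__setattr__(self, "fraction_means", fractions)
        if fractions.shape != (VOCABULARY_SIZE,):
            raise SkeletonValidationError(
                f"fraction_means must have length {VOCABULARY_SIZE}"
            )
        if (fractions < 0).any():
            raise SkeletonValidationError("fractions must be non-negative")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise SkeletonValidationError("fractions must sum to 1 within 1e-9")
        if self.mean_bout_frames < 1:
            raise SkeletonValidationError("mean_bout_frames must be >= 1")


def control_profile(label: str = "control-like") -> GroupProfile:
    """Uniform composition over the 40 classes (fraction 0.025 each)."""
    return GroupProfile(
        fraction_means=np.full(VOCABULARY_SIZE, 1.0 / VOCABULARY_SIZE), label=label
    )


def nonpod_profile() -> GroupProfile:
    """Non-delirious model animals: statistically control-like."""
    return control_profile(label="nonPOD-like")


def pod_profile(up: float = 0.040, down: float = 0.010) -> GroupProfile:
    """Delirium-like composition: 8 classes elevated, 6 reduced.

    ``up``/``down`` are the target fractions of the elevated and reduced
    classes; the remaining 26 classes share the leftover mass equally.
    The default shifts of 0.015 around the uniform 0.025 are at least three
    across-animal standard deviations at the default session length and
    bout duration.
    """
    fractions = np.empty(VOCABULARY_SIZE)
    rest = 1.0 - up * len(POD_UP_CLASSES) - down * len(POD_DOWN_CLASSES)
    n_rest = VOCABULARY_SIZE - len(POD_UP_CLASSES) - len(POD_DOWN_CLASSES)
    fractions[:] = rest / n_rest
    fractions[np.array(POD_UP_CLASSES) - 1] = up
    fractions[np.array(POD_DOWN_CLASSES) - 1] = down
    return GroupProfile(fraction_means=fractions, label="POD-like")


def generate_labels(
    profile: GroupProfile, n_frames: int, seed: int
) -> MovementLabelStream:
    """Bout-structured label stream matching a group profile.

    Classes with zero target fraction never occur.  Deterministic under a
    fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    fractions = profile.fraction_means
    support = np.flatnonzero(fractions > 0)
    # entry probability ~ fraction / mean bout length (scalar bout length
    # cancels); long-run occupancy then matches fraction_means
    entry = fractions[support] / fractions[support].sum()
    mean_bout = profile.mean_bout_frames
    # draw enough bouts to cover the stream with slack, then truncate
    chunks: list[np.ndarray] = []
    total = 0
    while total < n_frames:
        n_bouts = max(16, int(1.4 * (n_frames - total) / mean_bout))
        classes = support[rng.choice(support.size, size=n_bouts, p=entry)] + 1
        if mean_bout <= 1.0:
            lengths = np.ones(n_bouts, dtype=int)
        else:
            lengths = rng.geometric(1.0 / mean_bout, size=n_bouts)
        chunks.append(np.repeat(classes, lengths))
        total += int(lengths.sum())
    labels = np.concatenate(chunks)[:n_frames]
    return MovementLabelStream(labels=labels)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KinematicProfile:
    """Location parameters of one group's kinematics."""

    speed_scale: float = 2.0  # mm/frame
    height_scale: float = 27.0  # mm, torso height
    turn_rate: float = 0.15  # rad/frame heading diffusion
    label: str = "Hypo"

    def __post_init__(self) -> None:
        if self.speed_scale < 0:
            raise SkeletonValidationError("speed_scale must be >= 0")
        if self.height_scale <= 0 or self.turn_rate <= 0:
            raise SkeletonValidationError("scales must be positive")


def hyper_profile() -> KinematicProfile:
    """Hyperactive subtype: fast, tall posture."""
    return KinematicProfile(speed_scale=4.0, height_scale=32.0, turn_rate=0.2,
                            label="Hyper")


def hypo_profile() -> KinematicProfile:
    """Hypoactive subtype: slow, hunched posture."""
    return KinematicProfile(speed_scale=2.0, height_scale=24.0, turn_rate=0.15,
                            label="Hypo")


# fixed body plan: (forward, lateral) offsets from the torso centroid, mm,
# plus a nominal height; torso keypoints take their height from the profile
_BODY_PLAN: dict[str, tuple[float, float, float]] = {
    "nose": (45.0, 0.0, np.nan),
    "left_ear": (35.0, 10.0, np.nan),
    "right_ear": (35.0, -10.0, np.nan),
    "neck": (30.0, 0.0, np.nan),
    "left_front_limb": (20.0, 12.0, 12.0),
    "right_front_limb": (20.0, -12.0, 12.0),
    "left_hind_limb": (-15.0, 14.0, 12.0),
    "right_hind_limb": (-15.0, -14.0, 12.0),
    "left_front_claw": (22.0, 14.0, 3.0),
    "right_front_claw": (22.0, -14.0, 3.0),
    "left_hind_claw": (-18.0, 16.0, 3.0),
    "right_hind_claw": (-18.0, -16.0, 3.0),
    "back": (0.0, 0.0, np.nan),
    "root_tail": (-30.0, 0.0, np.nan),
    "middle_tail": (-55.0, 0.0, 8.0),
    "tail_tip": (-80.0, 0.0, 5.0),
}

#: keypoints whose height tracks the profile's height_scale
_TORSO_HEIGHTS = {
    "nose": 1.0,
    "left_ear": 1.05,
    "right_ear": 1.05,
    "neck": 1.0,
    "back": 1.0,
    "root_tail": 0.6,
}

#: planar reach of the body plan, mm (tail tip), used as the wall margin
_BODY_EXTENT = 85.0

_KEYPOINT_NOISE_MM = 1.0


def _fold_interval(x: np.ndarray, half: float) -> np.ndarray:
    """Reflect coordinates into [-half, half] (triangular-wave fold)."""
    period = 4.0 * half
    y = np.mod(x + half, period)
    return np.where(y <= 2 * half, y - half, 3 * half - y)


def _fold_into_arena(xy: np.ndarray, arena: ArenaSpec, margin: float) -> np.ndarray:
    half = arena.half_extent - margin
    if half <= 0:
        raise SkeletonValidationError(
            f"arena too small for the body plan (needs half extent > {margin} mm)"
        )
    out = xy.copy()
    if arena.shape == "square":
        out[:, 0] = _fold_interval(out[:, 0], half)
        out[:, 1] = _fold_interval(out[:, 1], half)
        return out
    r = np.hypot(out[:, 0], out[:, 1])
    r_fold = np.abs(_fold_interval(r, half))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, r_fold / r, 0.0)
    return out * scale[:, None]


def _skeleton_from_path(
    xy: np.ndarray,
    heading: np.ndarray,
    kin: KinematicProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assemble T x 16 x 3 frames from a centroid path and heading angle."""
    n = xy.shape[0]
    cos, sin = np.cos(heading), np.sin(heading)
    frames = np.empty((n, len(KEYPOINT_NAMES), 3))
    for k, name in enumerate(KEYPOINT_NAMES):
        fwd, lat, z_nominal = _BODY_PLAN[name]
        frames[:, k, 0] = xy[:, 0] + fwd * cos - lat * sin
        frames[:, k, 1] = xy[:, 1] + fwd * sin + lat * cos
        if name in _TORSO_HEIGHTS:
            frames[:, k, 2] = kin.height_scale * _TORSO_HEIGHTS[name]
        else:
            frames[:, k, 2] = z_nominal
    frames += rng.normal(0.0, _KEYPOINT_NOISE_MM, size=frames.shape)
    return frames


def generate_skeleton(
    kin: KinematicProfile,
    arena: ArenaSpec,
    n_frames: int,
    seed: int,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> SkeletonTrajectory:
    """Smoothed reflecting random walk with a rigid rotated body plan.

    The centroid follows heading-diffusion kinematics with gamma-distributed
    per-frame step lengths located at ``kin.speed_scale``; positions are
    folded back into the arena (inset by the body reach) so every keypoint
    stays inside the walls.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    heading = np.cumsum(rng.normal(0.0, kin.turn_rate, size=n_frames))
    heading = uniform_filter1d(heading, size=15, mode="nearest")
    # gamma(2, 1/2) has mean 1; smoothing keeps speeds positive and smooth
    steps = kin.speed_scale * rng.gamma(2.0, 0.5, size=n_frames)
    steps = uniform_filter1d(steps, size=5, mode="nearest")
    disp = np.column_stack((steps * np.cos(heading), steps * np.sin(heading)))
    xy = np.cumsum(disp, axis=0)
    xy -= xy[0]
    xy = _fold_into_arena(xy, arena, margin=_BODY_EXTENT + 5.0)
    frames = _skeleton_from_path(xy, heading, kin, rng)
    return SkeletonTrajectory(frames=frames, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# scheduled investigation sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduledBout:
    """One planned investigation bout (frames 1-based inclusive)."""

    start_frame: int
    end_frame: int
    role: str  # "familiar" | "novel"
    depth: str  # "deep" | "shallow"

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame or self.start_frame < 1:
            raise SkeletonValidationError("bout frames must satisfy 1 <= start <= end")
        if self.depth not in ("deep", "shallow"):
            raise SkeletonValidationError(f"unknown depth {self.depth!r}")


@dataclass(frozen=True)
class InvestigationSchedule:
    """Ground-truth bout plan for a synthetic object-investigation session."""

    bouts: tuple[ScheduledBout, ...]
    n_frames: int = DEFAULT_SESSION_FRAMES
    #: minimum separation between bouts, frames; must exceed the detector's
    #: bout-merging gap for exact schedule recovery
    min_separation: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "bouts", tuple(self.bouts))
        last_end = -self.min_separation
        for bout in sorted(self.bouts, key=lambda b: b.start_frame):
            if bout.start_frame - last_end <= self.min_separation:
                raise SkeletonValidationError(
                    f"bouts overlap or are closer than {self.min_separation} "
                    f"frames near frame {bout.start_frame}"
                )
            if bout.end_frame > self.n_frames:
                raise SkeletonValidationError("bout extends past session length")
            last_end = bout.end_frame

    def expected_durations(self, frame_rate: float = DEFAULT_FRAME_RATE
                           ) -> tuple[float, float]:
        """(T_deep, T_shallow) in seconds implied by the schedule."""
        t_deep = sum(b.end_frame - b.start_frame + 1
                     for b in self.bouts if b.depth == "deep") / frame_rate
        t_shallow = sum(b.end_frame - b.start_frame + 1
                        for b in self.bouts if b.depth == "shallow") / frame_rate
        return t_deep, t_shallow


#: investigation-geometry constants shared with the detector (mm)
APPROACH_DISTANCE_MM = 60.0
CLIMB_DISTANCE_MM = 30.0
_REST_CLEARANCE_MM = 80.0

_NOSE_FORWARD = _BODY_PLAN["nose"][0]  # 45 mm ahead of the centroid


def _rest_point(arena: ArenaSpec, margin: float) -> np.ndarray:
    """Grid point inside the arena maximizing clearance from all objects."""
    half = arena.half_extent - margin
    grid = np.linspace(-half, half, 41)
    gx, gy = np.meshgrid(grid, grid)
    pts = np.column_stack((gx.ravel(), gy.ravel()))
    pts = pts[arena.contains(pts + 0)]
    if arena.shape == "circle":
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= half]
    clearance = np.full(pts.shape[0], np.inf)
    for obj in arena.objects:
        d = np.hypot(pts[:, 0] - obj.centre[0], pts[:, 1] - obj.centre[1])
        clearance = np.minimum(clearance, d)
    best = pts[np.argmax(clearance)]
    if clearance.max() < _REST_CLEARANCE_MM + _NOSE_FORWARD + 20.0:
        raise SkeletonValidationError(
            "arena too small to keep the resting animal clear of the objects"
        )
    return best


def generate_investigation_session(
    schedule: InvestigationSchedule,
    arena: ArenaSpec,
    kin: KinematicProfile,
    seed: int,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> SkeletonTrajectory:
    """Session whose nose kinematics realize the scheduled bouts exactly.

    Outside scheduled bouts the animal idles around a rest point far from
    both objects (nose clearance > 80 mm).  During a shallow bout the nose
    holds ~40 mm from the object centre, oriented at it (approach rule only).
    A deep bout opens with the same approach frames and then climbs: nose
    within 30 mm and back height above the object top.
    """
    if not arena.objects:
        raise SkeletonValidationError("investigation sessions need arena objects")
    roles = {o.role for o in arena.objects}
    for bout in schedule.bouts:
        if bout.role not in roles:
            raise SkeletonValidationError(
                f"scheduled role {bout.role!r} not present in arena"
            )
    rng = np.random.default_rng(seed)
    n = schedule.n_frames
    rest = _rest_point(arena, margin=_BODY_EXTENT + 5.0)

    # baseline idling: small smooth wander about the rest point
    wander = np.cumsum(rng.normal(0.0, 0.6, size=(n, 2)), axis=0)
    wander = uniform_filter1d(wander, size=31, axis=0, mode="nearest")
    wander = np.clip(wander - wander.mean(axis=0), -10.0, 10.0)
    xy = rest[None, :] + wander
    heading = uniform_filter1d(
        np.cumsum(rng.normal(0.0, kin.turn_rate, size=n)), size=15, mode="nearest"
    )
    back_z = np.full(n, kin.height_scale)

    for bout in schedule.bouts:
        obj = arena.object_by_role(bout.role)
        centre = np.asarray(obj.centre)
        sl = slice(bout.start_frame - 1, bout.end_frame)
        length = bout.end_frame - bout.start_frame + 1
        # approach from the rest-point side of the object
        away = rest - centre
        away = away / np.linalg.norm(away)
        phi = np.arctan2(-away[1], -away[0])  # facing the object
        nose_dist = np.full(length, 42.0) + rng.normal(0.0, 2.0, size=length)
        z = np.full(length, kin.height_scale)
        if bout.depth == "deep":
            climb = slice(length // 2, length)
            n_climb = length - length // 2
            nose_dist[climb] = 18.0 + rng.normal(0.0, 1.5, size=n_climb)
            z[climb] = obj.top_height + 15.0
        nose_xy = centre[None, :] + np.outer(nose_dist, away)
        xy[sl] = nose_xy - _NOSE_FORWARD * np.array([np.cos(phi), np.sin(phi)])
        heading[sl] = phi
        back_z[sl] = z

    frames = _skeleton_from_path(xy, heading, kin, rng)
    # impose the per-frame torso height profile (climb frames raised)
    for name, rel in _TORSO_HEIGHTS.items():
        k = KEYPOINT_NAMES.index(name)
        frames[:, k, 2] = back_z * rel + rng.normal(
            0.0, _KEYPOINT_NOISE_MM, size=n
        )
    return SkeletonTrajectory(frames=frames, frame_rate=frame_rate)
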