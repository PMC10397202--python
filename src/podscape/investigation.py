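"""Geometric detection of object-investigation bouts, deep/shallow
classification, and the deep-versus-shallow preference (DSP) statistic.

A frame counts as investigating an object when either rule holds:

* approach (rule A): the 2-D nose-to-object-centre distance is below 60 mm
  and the neck-to-nose direction points at the object (the angle to the
  neck-to-object-centre direction is acute);
* climb (rule B): the 2-D nose distance is below 30 mm and the back is
  higher than the object top.  Rule B carries no orientation condition.

Contiguous investigating runs become bouts (runs separated by fewer than 5
frames are merged); a bout containing any rule-B frame is climb-triggered.
A bout is *deep* when it is climb-triggered or contains a movement label
from the configured deep-interaction classes (sniff/touch/crab); otherwise
it is *shallow*.  The preference statistic is

    DSP = arcsin((T_deep - T_shallow) / (T_deep + T_shallow)),

ranging over [-pi/2, pi/2]: pi/2 is exclusive deep investigation, -pi/2
exclusive shallow, 0 equal preference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .skeleton_io import (
    ArenaSpec,
    MovementLabelStream,
    ObjectSpec,
    SkeletonTrajectory,
    SkeletonValidationError,
)

#: Rule-A nose-to-object distance threshold, mm.
APPROACH_DISTANCE_MM = 60.0
#: Rule-B nose-to-object distance threshold, mm.
CLIMB_DISTANCE_MM = 30.0
#: Runs separated by fewer frames than this merge into one bout (~167 ms).
DEFAULT_MERGE_GAP = 5
#: Rule-A orientation cone half-angle (acute angle), rad.
DEFAULT_CONE_HALF_ANGLE = np.pi / 2

#: Default deep-interaction movement classes (sniff, touch, crab).
DEFAULT_DEEP_CLASSES: frozenset[int] = frozenset({35, 20, 6})


@dataclass(frozen=True)
class InvestigationBout:
    """One investigation bout; frames 1-based inclusive."""

    start_frame: int
    end_frame: int
    role: str
    trigger: str  # "approach" | "climb"
    depth: str = "unclassified"  # "deep" | "shallow" | "unclassified"

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise SkeletonValidationError("bout end before start")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class InvestigationRecord:
    """Session-level investigation summary."""

    bouts: tuple[InvestigationBout, ...]
    t_deep: float  # s
    t_shallow: float  # s
    per_object_time: dict[str, float]  # role -> s
    dsp: float | None  # rad; None when no investigation occurred

    def __post_init__(self) -> None:
        if self.t_deep < 0 or self.t_shallow < 0:
            raise SkeletonValidationError("investigation times must be >= 0")
        if self.dsp is not None and not -np.pi / 2 - 1e-12 <= self.dsp <= np.pi / 2 + 1e-12:
            raise SkeletonValidationError("DSP must lie in [-pi/2, pi/2]")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "start": b.start_frame, "end": b.end_frame,
                    "object": b.role, "trigger": b.trigger, "depth": b.depth,
                }
                for b in self.bouts
            ]
        )


def _investigation_mask(
    traj: SkeletonTrajectory,
    obj: ObjectSpec,
    approach_distance: float,
    climb_distance: float,
    cone_half_angle: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(investigating, rule_b) boolean masks over frames."""
    nose = traj.keypoint("nose")
    neck = traj.keypoint("neck")
    back = traj.keypoint("back")
    centre = np.asarray(obj.centre)
    nose_dist = np.hypot(nose[:, 0] - centre[0], nose[:, 1] - centre[1])
    # orientation: acute angle between neck->nose and neck->object (2-D)
    u = nose[:, :2] - neck[:, :2]
    v = centre[None, :] - neck[:, :2]
    dot = np.einsum("ij,ij->i", u, v)
    norms = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(norms > 0, dot / norms, -1.0)
    oriented = cos > np.cos(cone_half_angle)
    rule_a = (nose_dist < approach_distance) & oriented
    rule_b = (nose_dist < climb_distance) & (back[:, 2] > obj.top_height)
    return rule_a | rule_b, rule_b


def _mask_to_bouts(
    investigating: np.ndarray,
    rule_b: np.ndarray,
    role: str,
    merge_gap: int,
) -> list[InvestigationBout]:
    padded = np.concatenate(([False], investigating, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    bouts = []
    for s, e in merged:
        trigger = "climb" if rule_b[s : e + 1].any() else "approach"
        bouts.append(
            InvestigationBout(
                start_frame=s + 1, end_frame=e + 1, role=role, trigger=trigger
            )
        )
    return bouts


def detect_investigation(
    traj: SkeletonTrajectory,
    obj: ObjectSpec,
    approach_distance: float = APPROACH_DISTANCE_MM,
    climb_distance: float = CLIMB_DISTANCE_MM,
    cone_half_angle: float = DEFAULT_CONE_HALF_ANGLE,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> tuple[np.ndarray, list[InvestigationBout]]:
    """Per-frame investigation mask and merged bout list for one object."""
    investigating, rule_b = _investigation_mask(
        traj, obj, approach_distance, climb_distance, cone_half_angle
    )
    return investigating, _mask_to_bouts(investigating, rule_b, obj.role, merge_gap)


def classify_bouts(
    bouts: Sequence[InvestigationBout],
    labels: MovementLabelStream,
    deep_classes: Iterable[int] = DEFAULT_DEEP_CLASSES,
) -> list[InvestigationBout]:
    """Tag each bout deep or shallow.

    A bout is deep when climb-triggered, or when any of its frames carries
    a deep-interaction movement label; otherwise shallow.
    """
    deep_classes = frozenset(deep_classes)
    out = []
    for bout in bouts:
        if bout.end_frame > labels.n_frames:
            raise ValueError(
                f"labels end at frame {labels.n_frames}, bout ends at {bout.end_frame}"
            )
        frame_labels = labels.labels[bout.start_frame - 1 : bout.end_frame]
        deep = bout.trigger == "climb" or bool(
            np.isin(frame_labels, list(deep_classes)).any()
        )
        out.append(replace(bout, depth="deep" if deep else "shallow"))
    return out


def dsp(t_deep: float, t_shallow: float) -> float:
    """Deep-versus-shallow preference: arcsin((Td - Ts) / (Td + Ts)), rad."""
    if t_deep < 0 or t_shallow < 0:
        raise ValueError("investigation times must be >= 0")
    total = t_deep + t_shallow
    if total == 0:
        raise ValueError("DSP undefined: no investigation time")
    return float(np.arcsin((t_deep - t_shallow) / total))


def investigation_record(
    traj: SkeletonTrajectory,
    arena: ArenaSpec,
    labels: MovementLabelStream | None = None,
    deep_classes: Iterable[int] = DEFAULT_DEEP_CLASSES,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> InvestigationRecord:
    """Detect, classify and summarize investigation across all arena objects."""
    if not arena.objects:
        raise ValueError("arena has no objects to investigate")
    all_bouts: list[InvestigationBout] = []
    per_object: dict[str, float] = {}
    for obj in arena.objects:
        _, bouts = detect_investigation(traj, obj, merge_gap=merge_gap)
        if labels is not None:
            bouts = classify_bouts(bouts, labels, deep_classes)
        per_object[obj.role] = sum(b.n_frames for b in bouts) / traj.frame_rate
        all_bouts.extend(bouts)
    all_bouts.sort(key=lambda b: b.start_frame)
    t_deep = sum(b.n_frames for b in all_bouts if b.depth == "deep") / traj.frame_rate
    t_shallow = sum(
        b.n_frames for b in all_bouts if b.depth == "shallow"
    ) / traj.frame_rate
    value = dsp(t_deep, t_shallow) if t_deep + t_shallow > 0 else None
    return InvestigationRecord(
        bouts=tuple(all_bouts), t_deep=t_deep, t_shallow=t_shallow,
        per_object_time=per_object, dsp=value,
    )
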