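"""Movement-fraction vectors, discriminative-movement selection and the
classical open-field / object-recognition summary metrics.

The per-animal behavioural summary is the fraction of session frames spent
in each of the 40 movement classes.  Group differences per movement are
assessed with Welch's two-sample t-test under a Sidak family-wise
adjustment over the 40 classes; the significant movements define the
coordinates of the delirium-like behaviour space.

Classical metrics: centre time (seconds the torso spends within a central
radius of the circular open field), the recognition index
(t_novel - t_familiar) / (t_novel + t_familiar), and the composite Z score
— the sum of the control-standardized centre time, total exploration time
and recognition index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .skeleton_io import (
    ArenaSpec,
    MovementLabelStream,
    SkeletonTrajectory,
    SkeletonValidationError,
    VOCABULARY_SIZE,
)

#: Central-zone radius for open-field centre time, mm.
CENTRE_RADIUS_OFT_MM = 50.0
#: Central-zone radius used when feeding the composite Z score, mm.
CENTRE_RADIUS_COMPOSITE_MM = 100.0

#: Torso keypoint used as the animal's 2-D position.
POSITION_KEYPOINT = "back"


@dataclass(frozen=True)
class FractionVector:
    """Per-class frame fractions of one animal's session."""

    fractions: np.ndarray
    animal_id: str = ""
    paradigm: str = "OFT"

    def __post_init__(self) -> None:
        fractions = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", fractions)
        if fractions.shape != (VOCABULARY_SIZE,):
            raise SkeletonValidationError(
                f"fraction vector must have length {VOCABULARY_SIZE}"
            )
        if (fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-9:
            raise SkeletonValidationError("fractions must be >= 0 and sum to 1")


@dataclass(frozen=True)
class GroupComparison:
    """Per-movement group comparison with Sidak-adjusted p-values."""

    mean_a: np.ndarray
    mean_b: np.ndarray
    sem_a: np.ndarray
    sem_b: np.ndarray
    p_adjusted: np.ndarray
    selected: tuple[int, ...]  # 1-based movement classes
    alpha: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "movement": np.arange(1, VOCABULARY_SIZE + 1),
            "mean_a": self.mean_a, "sem_a": self.sem_a,
            "mean_b": self.mean_b, "sem_b": self.sem_b,
            "p_adjusted": self.p_adjusted,
            "selected": np.isin(np.arange(1, VOCABULARY_SIZE + 1), self.selected),
        })


@dataclass(frozen=True)
class CompositeZInputs:
    """One model animal's metrics plus the control group's reference moments."""

    centre_time: float
    total_exploration_time: float
    recognition_index: float
    control_mean: tuple[float, float, float]
    control_sd: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(sd <= 0 for sd in self.control_sd):
            raise SkeletonValidationError(
                "control SDs must be positive (degenerate control group)"
            )


def movement_fractions(
    labels: MovementLabelStream, animal_id: str = "", paradigm: str = "OFT"
) -> FractionVector:
    """Fraction of frames spent in each movement class."""
    counts = np.bincount(labels.labels, minlength=VOCABULARY_SIZE + 1)[1:]
    return FractionVector(
        fractions=counts / labels.n_frames, animal_id=animal_id, paradigm=paradigm
    )


def _stack(group: Iterable[FractionVector] | np.ndarray) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return np.atleast_2d(group)
    return np.vstack([fv.fractions for fv in group])


def select_significant_movements(
    group_a: Iterable[FractionVector] | np.ndarray,
    group_b: Iterable[FractionVector] | np.ndarray,
    alpha: float = 0.05,
) -> GroupComparison:
    """Per-movement Welch t-test with Sidak family-wise adjustment.

    The adjustment is p_adj = 1 - (1 - p)^40; movements with p_adj < alpha
    are selected.  Movements with zero variance in both groups and equal
    means are never selected.
    """
    a, b = _stack(group_a), _stack(group_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 animals per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
    p_adj = 1.0 - (1.0 - p) ** VOCABULARY_SIZE
    selected = tuple(int(k) for k in np.flatnonzero(p_adj < alpha) + 1)
    return GroupComparison(
        mean_a=a.mean(axis=0), mean_b=b.mean(axis=0),
        sem_a=stats.sem(a, axis=0), sem_b=stats.sem(b, axis=0),
        p_adjusted=p_adj, selected=selected, alpha=alpha,
    )


def centre_time(
    traj: SkeletonTrajectory,
    arena: ArenaSpec,
    centre_radius: float = CENTRE_RADIUS_OFT_MM,
    keypoint: str = POSITION_KEYPOINT,
) -> float:
    """Seconds the torso spends within ``centre_radius`` of the arena centre."""
    if arena.shape != "circle":
        raise ValueError("centre time is defined for the circular open field")
    xy = traj.keypoint(keypoint)[:, :2]
    inside = np.hypot(xy[:, 0], xy[:, 1]) < centre_radius
    return float(inside.sum() / traj.frame_rate)


def recognition_index(t_novel: float, t_familiar: float) -> float:
    """(t_novel - t_familiar) / (t_novel + t_familiar), in [-1, 1]."""
    total = t_novel + t_familiar
    if total <= 0:
        raise ValueError("no exploration time recorded for either object")
    return (t_novel - t_familiar) / total


def novel_time_ratio(t_novel: float, t_familiar: float) -> float:
    """Alternative index: novel-object time as a share of total exploration."""
    total = t_novel + t_familiar
    if total <= 0:
        raise ValueError("no exploration time recorded for either object")
    return t_novel / total


def composite_z(inputs: CompositeZInputs) -> float:
    """Sum of the three control-standardized behavioural metrics."""
    observed = (
        inputs.centre_time,
        inputs.total_exploration_time,
        inputs.recognition_index,
    )
    return float(sum(
        (x - mu) / sd
        for x, mu, sd in zip(observed, inputs.control_mean, inputs.control_sd)
    ))
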