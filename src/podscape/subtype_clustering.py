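"""Hyper/Hypo subtype clustering of POD animals from pose eigenvalues.

Each POD animal is represented by its pose-feature eigenvalue vector
(7 PMF descriptor statistics per feature).  Columns are standardized,
reduced to 3-D with the same t-SNE machinery as the delirium space, and
split with seeded k-means (k = 2).  The cluster whose speed-feature
summaries (back, nose, claw speeds) have the larger mean is named Hyper,
the other Hypo — the naming depends only on the speed statistics, so it is
stable under permutation of the k-means cluster indices.

``compare_subtype_features`` contrasts the two clusters feature by
feature: per-frame values are pooled across a cluster's animals, turned
into a group PMF, and compared with the resampling KS test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from . import delirium_space
from .pose_features import (
    DEFAULT_FEATURES,
    EigenvalueVector,
    KSResult,
    N_DESCRIPTORS,
    compute_pose_features,
    eigenvalue_vector,
    ks_resample_test,
    pmf,
)
from .skeleton_io import SkeletonTrajectory

#: Features whose eigenvalue blocks drive the Hyper/Hypo naming.
SPEED_FEATURES: tuple[str, ...] = (
    "back_speed",
    "nose_speed",
    "left_front_claw_speed",
    "right_front_claw_speed",
    "body_speed",
)


def eigenvalue_matrix(
    trajectories: Iterable[SkeletonTrajectory],
    feature_list: Sequence[str] = DEFAULT_FEATURES,
    bins: int = 50,
    on: str = "values",
) -> list[EigenvalueVector]:
    """Per-animal eigenvalue vectors for subtype clustering.

    Subtype separation is driven by kinematic location and scale (how fast,
    how high), so the descriptor statistics default to the distribution
    level (``on="values"``): statistics of the probability curve treated as
    a signal are invariant to shifts and rescalings of a feature because
    each animal's PMF spans its own observed range.
    """
    return [eigenvalue_vector(t, feature_list, bins=bins, on=on)
            for t in trajectories]


@dataclass(frozen=True)
class SubtypeResult:
    """Per-animal subtype assignment with the reduced coordinates."""

    subtypes: tuple[str, ...]  # "Hyper" | "Hypo" per animal
    coords: np.ndarray  # animals x 3
    cluster_indices: np.ndarray
    speed_scores: dict[int, float]  # cluster index -> mean speed summary


def _to_matrix(
    E: np.ndarray | Sequence[EigenvalueVector],
    feature_names: Sequence[str] | None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(E, np.ndarray):
        if feature_names is None:
            if E.shape[1] % N_DESCRIPTORS:
                raise ValueError("eigenvalue matrix width must be a multiple of 7")
            n = E.shape[1] // N_DESCRIPTORS
            feature_names = DEFAULT_FEATURES[:n]
        return np.asarray(E, dtype=float), tuple(feature_names)
    vectors = list(E)
    names = vectors[0].feature_names
    return np.vstack([v.values for v in vectors]), names


def cluster_subtypes(
    E: np.ndarray | Sequence[EigenvalueVector],
    seed: int = 0,
    k: int = 2,
    feature_names: Sequence[str] | None = None,
    neighbor_param: int = delirium_space.DEFAULT_NEIGHBOR_PARAM,
) -> SubtypeResult:
    """Standardize, embed to 3-D and k-means-split an eigenvalue matrix.

    With k = 2 the clusters are named Hyper/Hypo from the mean of the
    "mean" descriptor of every speed feature; for other k the raw cluster
    indices are returned as subtype names.
    """
    X, names = _to_matrix(E, feature_names)
    if X.shape[0] < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for k={k}")
    Z = StandardScaler().fit_transform(X)
    coords = delirium_space.embed(Z, seed=seed, neighbor_param=neighbor_param)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    idx = km.fit_predict(coords)

    # per-cluster mean of the speed features' "mean" statistic (block slot 0)
    speed_cols = [
        names.index(f) * N_DESCRIPTORS
        for f in SPEED_FEATURES
        if f in names
    ]
    scores = {
        int(c): float(X[idx == c][:, speed_cols].mean()) if speed_cols else 0.0
        for c in np.unique(idx)
    }
    if k == 2:
        hyper = max(scores, key=lambda c: scores[c])
        subtypes = tuple("Hyper" if c == hyper else "Hypo" for c in idx)
    else:
        subtypes = tuple(f"cluster{c}" for c in idx)
    return SubtypeResult(
        subtypes=subtypes, coords=coords, cluster_indices=idx, speed_scores=scores
    )


def compare_subtype_features(
    group_a: Iterable[SkeletonTrajectory],
    group_b: Iterable[SkeletonTrajectory],
    feature_list: Sequence[str] = DEFAULT_FEATURES,
    n_resample: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    independent_draws: bool = True,
) -> dict[str, KSResult]:
    """Per-feature KS comparison between two groups of animals.

    Per-frame feature values are pooled (concatenated) across each group's
    animals before histogramming.  Each feature's resampling draw gets its
    own derived seed; by default the two group draws are independent.
    """
    pooled_a: dict[str, list[np.ndarray]] = {f: [] for f in feature_list}
    pooled_b: dict[str, list[np.ndarray]] = {f: [] for f in feature_list}
    for traj in group_a:
        for series in compute_pose_features(traj, feature_list):
            pooled_a[series.feature_name].append(series.values)
    for traj in group_b:
        for series in compute_pose_features(traj, feature_list):
            pooled_b[series.feature_name].append(series.values)
    results: dict[str, KSResult] = {}
    for i, feature in enumerate(feature_list):
        curve_a = pmf(np.concatenate(pooled_a[feature]))
        curve_b = pmf(np.concatenate(pooled_b[feature]))
        seed_a = seed * 1000 + 2 * i
        seed_b = seed_a + 1 if independent_draws else seed_a
        results[feature] = ks_resample_test(
            curve_a, curve_b, n_resample=n_resample, alpha=alpha,
            seed=seed_a, seed_b=seed_b,
        )
    return results
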