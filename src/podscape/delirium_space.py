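"""POD/non-POD diagnosis and the low-dimensional delirium-like behaviour
space.

Diagnosis starts from the 40-class movement-fraction vectors of the model
and control animals.  Fractions are z-scored per movement across all
samples and cut into two clusters by Ward agglomerative clustering (the
clustergram view).  The cluster enriched for control samples anchors the
"normal" pattern; model animals fall in the non-POD class unless their
cluster is strongly depleted of control samples, in which case they are
POD.  The depletion rule (cluster control share below half the overall
control share, by default) keeps a homogeneous model group from being
split into artificial cases.

The behaviour space proper embeds the selected (discriminative) movement
fractions into 3-D with t-SNE (perplexity 6), fits a max-margin linear
boundary between the diagnosed groups, and reports each sample's signed
distance to that plane — a one-dimensional severity axis oriented so POD
is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from sklearn.manifold import TSNE
from sklearn.svm import SVC

from .behavior_metrics import FractionVector
from .skeleton_io import SkeletonValidationError

DEFAULT_NEIGHBOR_PARAM = 6
EMBED_DIM = 3


@dataclass(frozen=True)
class Hyperplane:
    """Linear decision boundary w . y + b = 0 in the embedded space."""

    w: np.ndarray
    b: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if np.linalg.norm(w) == 0:
            raise SkeletonValidationError("hyperplane normal must be nonzero")


@dataclass(frozen=True)
class DiagnosisResult:
    """Per-animal POD/non-POD assignment from the clustergram cut."""

    labels: tuple[str, ...]  # per model sample: "POD" | "nonPOD"
    cluster_assignments: np.ndarray  # over model + control samples
    control_cluster: int
    linkage: np.ndarray

    @property
    def pod_mask(self) -> np.ndarray:
        return np.array([lab == "POD" for lab in self.labels])


@dataclass(frozen=True)
class DeliriumSpace:
    """Embedded behaviour space with its decision boundary."""

    X: np.ndarray  # samples x selected-movement fractions
    Y: np.ndarray  # samples x 3
    hyperplane: Hyperplane
    projection_values: np.ndarray  # signed distances, POD-positive
    raw_scores: np.ndarray  # unnormalized w . y + b
    labels: tuple[str, ...]


def _stack(group: Iterable[FractionVector] | np.ndarray) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return np.atleast_2d(np.asarray(group, dtype=float))
    return np.vstack([fv.fractions for fv in group])


def diagnose_pod(
    model: Iterable[FractionVector] | np.ndarray,
    control: Iterable[FractionVector] | np.ndarray,
    seed: int = 0,
    control_share_ratio: float = 0.5,
) -> DiagnosisResult:
    """Split model animals into POD / non-POD against the control pattern.

    ``seed`` is accepted for interface uniformity; the Ward cut itself is
    deterministic.  A model cluster is called POD when its within-cluster
    control share falls below ``control_share_ratio`` times the overall
    control share; the cluster holding the larger share of controls is
    always non-POD.
    """
    m, c = _stack(model), _stack(control)
    if m.shape[0] == 0 or c.shape[0] == 0:
        raise ValueError("both model and control sets must be non-empty")
    X = np.vstack([m, c])
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).all():
        raise ValueError("degenerate clustering: all samples identical")
    mu = X.mean(axis=0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    linkage = hierarchy.linkage(Z, method="ward")
    assignments = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    is_control = np.zeros(X.shape[0], dtype=bool)
    is_control[m.shape[0] :] = True
    overall_share = is_control.mean()
    shares = {
        k: is_control[assignments == k].mean() for k in np.unique(assignments)
    }
    anchor = max(shares, key=lambda k: shares[k])  # control-enriched cluster
    labels = []
    for k in assignments[: m.shape[0]]:
        depleted = shares[k] < control_share_ratio * overall_share
        labels.append("POD" if (k != anchor and depleted) else "nonPOD")
    return DiagnosisResult(
        labels=tuple(labels),
        cluster_assignments=assignments,
        control_cluster=int(anchor),
        linkage=linkage,
    )


def embed(
    X: np.ndarray, seed: int = 0, neighbor_param: int = DEFAULT_NEIGHBOR_PARAM
) -> np.ndarray:
    """3-D t-SNE embedding of a fraction (or feature) matrix.

    ``neighbor_param`` maps onto t-SNE's perplexity.  PCA initialization and
    the exact gradient make the embedding deterministic under a fixed seed
    and equivariant (to numerical tolerance) under sample permutation.  The
    small fixed learning rate and long iteration budget are tuned for the
    few-dozen-sample cohorts this space is built from; large adaptive steps
    shatter well-separated clusters at this scale.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("embedding needs at least 4 samples")
    if X.ndim != 2 or X.shape[1] < EMBED_DIM:
        raise ValueError(
            f"embedding needs at least {EMBED_DIM} feature columns"
        )
    if X.shape[0] <= neighbor_param:
        raise ValueError(
            f"need more than neighbor_param={neighbor_param} samples, got {X.shape[0]}"
        )
    tsne = TSNE(
        n_components=EMBED_DIM,
        perplexity=neighbor_param,
        init="pca",
        method="exact",
        learning_rate=10.0,
        early_exaggeration=6.0,
        max_iter=2000,
        random_state=seed,
    )
    return tsne.fit_transform(X)


def fit_boundary(Y: np.ndarray, labels: Sequence[str] | np.ndarray) -> Hyperplane:
    """Max-margin (soft-margin) linear separator in the embedded space."""
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("boundary fitting needs exactly two classes present")
    clf = SVC(kernel="linear")
    clf.fit(np.asarray(Y, dtype=float), labels)
    return Hyperplane(w=clf.coef_[0].copy(), b=float(clf.intercept_[0]))


def project(
    Y: np.ndarray,
    hyperplane: Hyperplane,
    positive_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Signed distance of each embedded point to the boundary.

    With ``positive_mask`` (e.g. the POD animals), the sign convention is
    flipped if needed so the masked group's centroid is positive.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    norm = np.linalg.norm(hyperplane.w)
    values = (Y @ hyperplane.w + hyperplane.b) / norm
    if positive_mask is not None and values[np.asarray(positive_mask)].mean() < 0:
        values = -values
    return values


def build_delirium_space(
    model: Iterable[FractionVector] | np.ndarray,
    control: Iterable[FractionVector] | np.ndarray,
    selected: Sequence[int],
    seed: int = 0,
    neighbor_param: int = DEFAULT_NEIGHBOR_PARAM,
) -> tuple[DiagnosisResult, DeliriumSpace]:
    """Full diagnosis + embedding + boundary + projection for model animals.

    ``selected`` lists the discriminative movement classes (1-based) whose
    fractions span the behaviour space.
    """
    diagnosis = diagnose_pod(model, control, seed=seed)
    m = _stack(model)
    cols = np.asarray(selected, dtype=int) - 1
    X = m[:, cols]
    Y = embed(X, seed=seed, neighbor_param=neighbor_param)
    plane = fit_boundary(Y, diagnosis.labels)
    raw = Y @ plane.w + plane.b
    values = project(Y, plane, positive_mask=diagnosis.pod_mask)
    return diagnosis, DeliriumSpace(
        X=X, Y=Y, hyperplane=plane, projection_values=values,
        raw_scores=raw, labels=diagnosis.labels,
    )
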