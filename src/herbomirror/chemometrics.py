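"""Ratio features, SVD-based PCA, k-means grouping and loading ranking.

The central chemometric idea is scale invariance: within one sample, the
ratio of every peak height to every other peak height is unchanged when
the whole sample is diluted or concentrated. An aligned matrix of n peaks
therefore yields n(n-1)/2 ratio features per sample that carry the
compositional fingerprint but not the overall concentration. PCA on these
features, followed by k-means with k groups specified in the space of the
first two principal components, recovers compositional grouping that raw
peak heights can miss for samples of atypical concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .chrom import AlignedPeakMatrix

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "ClusterResult",
    "LoadingRanking",
    "ratio_transform",
    "pca",
    "cluster_scores",
    "adjusted_rand",
    "top_loading_features",
]


@dataclass
class FeatureMatrix:
    """Samples x features matrix with identified rows and columns."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    kind: str = "peak_heights"  # peak_heights | peak_ratios | expression_means

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape must be (n_samples, n_features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")


@dataclass
class PCAModel:
    """PCA fitted by SVD of the (optionally centered/scaled) sample matrix."""

    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # retained features x components
    explained_fraction: np.ndarray
    centered: bool
    scaled: bool
    sample_ids: list[str]
    feature_ids: list[str]  # retained features, in order
    dropped_features: list[str]  # zero-variance features removed before scaling
    feature_means: np.ndarray | None = None  # over retained features
    feature_sds: np.ndarray | None = None

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project new samples (rows over the retained features) into score space."""
        v = np.asarray(values, dtype=float)
        if self.centered and self.feature_means is not None:
            v = v - self.feature_means
        if self.scaled and self.feature_sds is not None:
            v = v / self.feature_sds
        return v @ self.loadings


@dataclass
class ClusterResult:
    labels: np.ndarray
    centers: np.ndarray
    k: int
    inertia: float
    seed: int


class LoadingRanking(NamedTuple):
    feature_ids: list[str]
    projections: np.ndarray
    degenerate: bool


def ratio_transform(
    m: AlignedPeakMatrix,
    floor: float | None = None,
    log_scale: bool = True,
) -> FeatureMatrix:
    """Within-sample pairwise peak-height ratios.

    For each unordered pair of consensus peaks (i earlier in rt than j) the
    feature is h_i' / h_j' with h' = max(h, floor); n peaks give
    n(n-1)/2 features. Undetected peaks (height 0) are lifted to the
    floor, which defaults to half the smallest nonzero height in the
    matrix, so presence/absence still carries signal without division by
    zero. ``log_scale`` returns log2 ratios (symmetric around 0).
    """
    n = m.n_peaks
    if n < 2:
        raise ValueError("need at least 2 consensus peaks for ratios")
    if floor is None:
        nonzero = m.heights[m.heights > 0]
        if nonzero.size == 0:
            raise ValueError("all-zero peak matrix")
        floor = float(nonzero.min()) / 2.0
    if floor <= 0:
        raise ValueError("floor must be positive")
    h = np.maximum(m.heights, floor)
    iu, ju = np.triu_indices(n, k=1)
    ratios = h[:, iu] / h[:, ju]
    if log_scale:
        ratios = np.log2(ratios)
    ids = [f"rt_{m.consensus_rt[i]:.4f}/rt_{m.consensus_rt[j]:.4f}" for i, j in zip(iu, ju)]
    return FeatureMatrix(ratios, ids, list(m.sample_ids), kind="peak_ratios")


def pca(x: FeatureMatrix, center: bool = True, scale: bool = True) -> PCAModel:
    """PCA via singular value decomposition of the samples x features matrix.

    Features are centered and, if ``scale``, divided by their sample
    standard deviation. Zero-variance features are dropped beforehand
    (scaling by 0 is undefined); they are recorded on the model. Scores
    are U*S over samples; explained fractions are sigma_k^2 / sum sigma^2.
    Component signs are fixed so each component's largest-magnitude
    loading is positive, making runs reproducible.
    """
    if len(x.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    v = x.values
    sd = v.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(x.feature_ids, keep) if not k]
    v = v[:, keep]
    if v.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant features")
    means = v.mean(axis=0)
    if center:
        v = v - means
    if scale:
        v = v / sd[keep]
    u, s, vt = np.linalg.svd(v, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for k in range(s.size):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    total = float(np.sum(s**2))
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    return PCAModel(
        scores=scores,
        loadings=vt.T,
        explained_fraction=explained,
        centered=center,
        scaled=scale,
        sample_ids=list(x.sample_ids),
        feature_ids=[f for f, k in zip(x.feature_ids, keep) if k],
        dropped_features=dropped,
        feature_means=means,
        feature_sds=sd[keep],
    )


def cluster_scores(
    p: PCAModel,
    k: int = 3,
    n_pc: int = 2,
    restarts: int = 100,
    seed: int = 0,
) -> ClusterResult:
    """k-means partition of the first ``n_pc`` score columns.

    Best of ``restarts`` k-means++ initializations by within-cluster sum
    of squares; deterministic given the seed.
    """
    n_samples = p.scores.shape[0]
    if k > n_samples:
        raise ValueError("k cannot exceed the number of samples")
    pts = p.scores[:, : min(n_pc, p.scores.shape[1])]
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed)
    labels = km.fit_predict(pts)
    return ClusterResult(
        labels=labels.astype(int),
        centers=km.cluster_centers_,
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
    )


def adjusted_rand(labels_a: Sequence, labels_b: Sequence) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))


def top_loading_features(
    p: PCAModel,
    cluster: ClusterResult,
    group: int,
    top_n: int | None = None,
    n_pc: int = 2,
) -> LoadingRanking:
    """Rank features by loading projection onto a cluster's center direction.

    The loadings plot interpretation: a feature whose loading vector points
    toward a group's score-space centroid is "responsible" for that group's
    separation. Features are ranked by the dot product of their first
    ``n_pc`` loading components with the unit vector toward the group
    center. A flat ranking (all projections equal) is flagged degenerate.
    """
    if not 0 <= group < cluster.k:
        raise ValueError(f"unknown group {group}")
    center = cluster.centers[group][:n_pc]
    norm = np.linalg.norm(center)
    if norm == 0:
        direction = np.zeros_like(center)
    else:
        direction = center / norm
    proj = p.loadings[:, : len(direction)] @ direction
    degenerate = bool(np.ptp(proj) < 1e-12)
    order = np.argsort(-proj, kind="stable")
    if top_n is not None:
        order = order[:top_n]
    return LoadingRanking(
        feature_ids=[p.feature_ids[i] for i in order],
        projections=proj[order],
        degenerate=degenerate,
    )
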