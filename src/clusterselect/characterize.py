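"""Stage 1: measure dataset and cluster-structure characteristics.

Dataset characteristics (size, dimensionality) come straight from the matrix
shape. Cluster-structure characteristics need labels — true ones when
available, or provisional ones from a default clusterer — and are assessed
the way an analyst would read a 2-component PCA score plot: elongation in the
projection, balance / singletons / density / outliers in full space.

All qualitative judgements ("small", "high-dimensional", "unbalanced", ...)
are operationalized through configurable thresholds; the defaults are stated
in :class:`Thresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .dataset import DatasetMatrix, OUTLIER_LABEL
from .kb import Characteristic, CLUSTER_CHARACTERISTICS


@dataclass(frozen=True)
class Thresholds:
    """Operational cut-offs turning measured quantities into flags.

    small_max_samples:
        A dataset is *small* when ``n_samples`` is strictly below this
        (default 1000 — spectroscopy collections are typically tens to
        hundreds of samples).
    high_dim_min_features:
        *High-dimensional* when ``n_features`` strictly exceeds this
        (default 50, the conventional cut-off for cluster analysis).
    balance:
        Clusters are *uneven* when min/max cluster size falls below this.
    density_ratio:
        *Variable density* when the max/min ratio of per-cluster mean
        nearest-neighbour distances exceeds this.
    elongation:
        *Non-spherical* when any cluster's sqrt(lambda1/lambda2) axis ratio
        (in the 2-component projection) exceeds this.
    outlier_fraction:
        *Noise/outliers present* when the detected outlier fraction exceeds
        this.
    outlier_nn_mad_multiplier:
        A point is an outlier when its within-cluster nearest-neighbour
        distance exceeds the cluster median by more than this many
        (normal-consistent, i.e. 1.4826-scaled) MADs. Nearest-neighbour
        distances are heavy-tailed even in clean Gaussian clusters — the
        periphery is always sparse — so the multiplier is deliberately
        large; 10 gives essentially no false detections on clean clusters
        while still catching detached points.
    """

    small_max_samples: int = 1000
    high_dim_min_features: int = 50
    balance: float = 0.5
    density_ratio: float = 2.0
    elongation: float = 2.0
    outlier_fraction: float = 0.02
    outlier_nn_mad_multiplier: float = 10.0


@dataclass
class DatasetCharacteristics:
    n_samples: int
    n_features: int
    n_classes: int | None
    small_dataset: bool
    high_dimensional: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PCAResult:
    """Scores and per-axis explained-variance fractions of a PCA projection."""

    scores: np.ndarray
    explained_fraction: np.ndarray


@dataclass
class ClusterStructure:
    """Measured cluster-structure characteristics of a labelled dataset."""

    n_clusters: int
    sizes: np.ndarray
    balance_ratio: float
    has_single_point_cluster: bool
    density_variation_ratio: float
    max_elongation: float
    outlier_fraction: float
    flags: dict  # Characteristic -> bool, the five cluster characteristics
    estimated: bool = False

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "sizes": self.sizes.tolist(),
            "balance_ratio": self.balance_ratio,
            "has_single_point_cluster": self.has_single_point_cluster,
            "density_variation_ratio": self.density_variation_ratio,
            "max_elongation": self.max_elongation,
            "outlier_fraction": self.outlier_fraction,
            "flags": {c.value: bool(v) for c, v in self.flags.items()},
            "estimated": self.estimated,
        }


def characterize_dataset(
    m: DatasetMatrix, thresholds: Thresholds = Thresholds()
) -> DatasetCharacteristics:
    """Size/dimensionality characteristics of the matrix itself."""
    if m.n_samples == 0 or m.n_features == 0:
        raise ValueError("empty matrix")
    return DatasetCharacteristics(
        n_samples=m.n_samples,
        n_features=m.n_features,
        n_classes=m.n_classes,
        small_dataset=m.n_samples < thresholds.small_max_samples,
        high_dimensional=m.n_features > thresholds.high_dim_min_features,
    )


def project_pca(m: DatasetMatrix, q: int = 2) -> PCAResult:
    """Mean-centred projection onto the top-q principal axes.

    Centring only — any scaling belongs to the preprocessing step. The
    explained fractions are each axis's share of total variance, summing to
    1 at full rank.
    """
    max_q = min(m.n_samples - 1, m.n_features)
    if not 1 <= q <= max_q:
        raise ValueError(f"q must be in [1, {max_q}] for this matrix, got {q}")
    pca = PCA(n_components=q, svd_solver="full")
    scores = pca.fit_transform(m.values)
    return PCAResult(scores=scores, explained_fraction=pca.explained_variance_ratio_)


def _nn_distances(points: np.ndarray) -> np.ndarray:
    """Distance of each point to its nearest neighbour within the set."""
    dm = squareform(pdist(points))
    np.fill_diagonal(dm, np.inf)
    return dm.min(axis=1)


def characterize_clusters(
    m: DatasetMatrix,
    labels: np.ndarray | None = None,
    thresholds: Thresholds = Thresholds(),
) -> ClusterStructure:
    """Measure cluster-structure characteristics from a labelled matrix.

    Elongation is assessed in the 2-component PCA projection (mirroring
    score-plot inspection); densities and outliers in the full feature
    space. Points labelled :data:`OUTLIER_LABEL` are counted as outliers,
    not as a cluster.
    """
    labels = np.asarray(m.labels if labels is None else labels)
    if labels.shape != (m.n_samples,):
        raise ValueError("labels must be one per sample")
    member = labels != OUTLIER_LABEL
    cluster_ids = np.unique(labels[member])
    if cluster_ids.size == 0:
        raise ValueError("no non-outlier clusters present")

    sizes = np.array([int(np.sum(labels == c)) for c in cluster_ids])
    balance_ratio = float(sizes.min() / sizes.max())
    has_singleton = bool(sizes.min() == 1)

    # per-cluster density: mean nearest-neighbour distance, full space;
    # size-1 clusters carry no density information and are excluded
    mean_nn = []
    detected_outliers = int(np.sum(~member))
    for c in cluster_ids:
        pts = m.values[labels == c]
        if len(pts) < 2:
            continue
        nn = _nn_distances(pts)
        mean_nn.append(float(nn.mean()))
        med = np.median(nn)
        mad = 1.4826 * np.median(np.abs(nn - med))
        if mad > 0:
            cut = med + thresholds.outlier_nn_mad_multiplier * mad
            detected_outliers += int(np.sum(nn > cut))
    if mean_nn and min(mean_nn) > 0:
        density_ratio = float(max(mean_nn) / min(mean_nn))
    else:
        density_ratio = 1.0
    outlier_fraction = detected_outliers / m.n_samples

    # elongation in the 2-component projection, per cluster with >= 3 points
    max_elong = 1.0
    if m.n_features >= 2 and m.n_samples >= 3:
        scores = project_pca(m, q=min(2, m.n_features, m.n_samples - 1)).scores
        if scores.shape[1] == 2:
            for c in cluster_ids:
                pts = scores[labels == c]
                if len(pts) < 3:
                    continue
                cov = np.cov(pts, rowvar=False)
                lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
                if lam[1] > 1e-12 * lam[0]:
                    max_elong = max(max_elong, float(np.sqrt(lam[0] / lam[1])))
                elif lam[0] > 0:
                    max_elong = np.inf

    flags = {
        Characteristic.UNEVEN_CLUSTER_SIZE: balance_ratio < thresholds.balance,
        Characteristic.SINGLE_POINT_CLUSTER: has_singleton,
        Characteristic.VARIABLE_CLUSTER_DENSITY: density_ratio > thresholds.density_ratio,
        Characteristic.NON_SPHERICAL_SHAPE: max_elong > thresholds.elongation,
        Characteristic.ROBUST_NOISE_OUTLIERS: outlier_fraction > thresholds.outlier_fraction,
    }
    return ClusterStructure(
        n_clusters=len(cluster_ids),
        sizes=sizes,
        balance_ratio=balance_ratio,
        has_single_point_cluster=has_singleton,
        density_variation_ratio=density_ratio,
        max_elongation=max_elong,
        outlier_fraction=outlier_fraction,
        flags=flags,
    )


def estimate_structure_unlabelled(
    m: DatasetMatrix, k: int, thresholds: Thresholds = Thresholds()
) -> ClusterStructure:
    """Cluster-structure estimate for unlabelled data.

    Obtains provisional labels from Ward-linkage agglomeration at ``k``
    clusters, then measures structure as for labelled data; the result is
    marked ``estimated``.
    """
    from sklearn.cluster import AgglomerativeClustering

    if not 1 <= k <= m.n_samples:
        raise ValueError(f"k must be in [1, {m.n_samples}], got {k}")
    if k == m.n_samples:
        provisional = np.arange(m.n_samples)
    else:
        provisional = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(
            m.values
        )
    cs = characterize_clusters(m, provisional, thresholds)
    cs.estimated = True
    return cs


def derive_requirement_profile(
    dc: DatasetCharacteristics, cs: ClusterStructure
) -> dict:
    """Mark each of the seven data/cluster characteristics on or off.

    The four algorithm-side characteristics (hierarchical output, parameter
    simplicity, determinism, efficiency) reflect the analysis context, not
    the data, and are left to the user at Stage 2.
    """
    profile = {
        Characteristic.SMALL_DATASETS: dc.small_dataset,
        Characteristic.HIGH_DIMENSIONS: dc.high_dimensional,
    }
    for c in CLUSTER_CHARACTERISTICS:
        profile[c] = bool(cs.flags[c])
    return profile
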