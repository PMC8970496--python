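"""Stage 4: cluster validity indices and the algorithms x datasets grid.

The external index is the V-measure: with class entropy H(C), cluster
entropy H(K) and conditional entropies from the class x cluster contingency
table,

    h = 1 - H(C|K)/H(C)        (homogeneity: each cluster one class)
    c = 1 - H(K|C)/H(K)        (completeness: each class one cluster)
    V_beta = (1 + beta) h c / (beta h + c)

with the conventions h = 1 when H(C) = 0, c = 1 when H(K) = 0 and V = 0
when beta h + c = 0. beta = 1 gives the harmonic mean of h and c. Entropies
use the natural logarithm; every index here is a ratio, so the base cancels.

Internal indices (no ground truth needed): mean silhouette, Davies-Bouldin
and Dunn.

Density-based algorithms may leave points unassigned (noise). Before
external scoring, noise points are mapped either to one extra cluster
(default) or to per-point singleton clusters — the convention is explicit
because it visibly changes the score when noise is plentiful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn import metrics as skmetrics
from sklearn.metrics.cluster import contingency_matrix

from .dataset import DatasetMatrix
from .runners import AlgorithmSpec, NOISE_LABEL, AlgorithmError, run, tune_to_k

#: Noise fraction above which a grid cell is annotated as excess noise.
EXCESS_NOISE_FRACTION = 0.25


def _check_pair(true_labels, pred_labels):
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.size} true vs {p.size} predicted")
    return t, p


def contingency(true_labels, pred_labels) -> np.ndarray:
    """Class x cluster count table; entry (i, j) counts points with the
    i-th class and j-th cluster label (labels in sorted order)."""
    t, p = _check_pair(true_labels, pred_labels)
    return contingency_matrix(t, p)


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    nz = counts[counts > 0]
    return float(-(nz / n * np.log(nz / n)).sum())


def _conditional_entropy(table: np.ndarray) -> float:
    """H(rows | columns) from a contingency table, natural log."""
    n = table.sum()
    h = 0.0
    for j in range(table.shape[1]):
        col = table[:, j]
        nj = col.sum()
        if nj == 0:
            continue
        nz = col[col > 0]
        h -= float((nz / n * np.log(nz / nj)).sum())
    return h


def homogeneity(true_labels, pred_labels) -> float:
    """1 - H(class|cluster)/H(class); 1.0 when the truth has one class."""
    table = contingency(true_labels, pred_labels)
    h_class = _entropy(table.sum(axis=1))
    if h_class == 0:
        return 1.0
    return 1.0 - _conditional_entropy(table) / h_class


def completeness(true_labels, pred_labels) -> float:
    """Dual of homogeneity with class and cluster roles swapped."""
    return homogeneity(pred_labels, true_labels)


@dataclass(frozen=True)
class VMeasureResult:
    h: float
    c: float
    beta: float
    v: float


def v_measure(true_labels, pred_labels, beta: float = 1.0) -> VMeasureResult:
    """Combined homogeneity/completeness score in [0, 1].

    1.0 iff the prediction is a bijective relabelling of the truth; beta > 1
    weights completeness more, beta < 1 homogeneity more.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    h = homogeneity(true_labels, pred_labels)
    c = completeness(true_labels, pred_labels)
    denom = beta * h + c
    v = (1.0 + beta) * h * c / denom if denom > 0 else 0.0
    return VMeasureResult(h=h, c=c, beta=beta, v=v)


def resolve_noise(labels, convention: str = "cluster") -> np.ndarray:
    """Map noise-sentinel points to scoreable cluster labels.

    ``cluster``: all noise points become one additional cluster;
    ``singletons``: each noise point becomes its own cluster.
    """
    labels = np.asarray(labels, dtype=int).copy()
    noise = labels == NOISE_LABEL
    if not noise.any():
        return labels
    base = labels.max() + 1 if (~noise).any() else 0
    if convention == "cluster":
        labels[noise] = base
    elif convention == "singletons":
        labels[noise] = base + np.arange(int(noise.sum()))
    else:
        raise ValueError("noise convention must be 'cluster' or 'singletons'")
    return labels


# ----------------------------------------------------------------- internal


def _check_internal(m: DatasetMatrix, labels, min_clusters: int = 2):
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (m.n_samples,):
        raise ValueError("labels must be one per sample")
    ids = np.unique(labels)
    if ids.size < min_clusters:
        raise ValueError(f"need at least {min_clusters} clusters, got {ids.size}")
    return labels, ids


def silhouette(m: DatasetMatrix, labels) -> float:
    """Mean silhouette over points; singleton-cluster points score 0."""
    labels, _ = _check_internal(m, labels)
    return float(skmetrics.silhouette_score(m.values, labels))


def davies_bouldin(m: DatasetMatrix, labels) -> float:
    """Davies-Bouldin index (lower is better).

    Mean over clusters of the worst (s_i + s_j)/d_ij, with s the mean
    distance to the centroid and d the centroid separation. Coincident
    centroids make a pair's ratio undefined and raise.
    """
    labels, ids = _check_internal(m, labels)
    centroids = np.array([m.values[labels == c].mean(axis=0) for c in ids])
    sep = squareform(pdist(centroids))
    iu = np.triu_indices(len(ids), k=1)
    if np.any(sep[iu] == 0):
        raise ValueError("coincident cluster centroids: index undefined for that pair")
    return float(skmetrics.davies_bouldin_score(m.values, labels))


def dunn(m: DatasetMatrix, labels) -> float:
    """Dunn index (higher is better): minimum single-linkage inter-cluster
    distance over maximum intra-cluster diameter."""
    labels, ids = _check_internal(m, labels)
    dm = squareform(pdist(m.values))
    diameters = [
        dm[np.ix_(labels == c, labels == c)].max() for c in ids
    ]
    max_diameter = max(diameters)
    if max_diameter == 0:
        raise ValueError("all clusters are singletons/coincident: zero diameter")
    min_between = min(
        dm[np.ix_(labels == a, labels == b)].min()
        for ai, a in enumerate(ids)
        for b in ids[ai + 1 :]
    )
    return float(min_between / max_diameter)


# --------------------------------------------------------------------- grid


@dataclass
class EvaluationTable:
    """Algorithms x datasets V-measure grid with per-group totals.

    ``scores`` has one row per algorithm and one column per dataset;
    ``group_totals`` sums each algorithm's scores over each named dataset
    group (missing cells count as 0 and are annotated). ``annotations``
    maps (algorithm, dataset) to flags such as excess noise, failure, or an
    unreachable cluster count.
    """

    scores: pd.DataFrame
    group_totals: pd.DataFrame
    annotations: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        joined = self.scores.join(self.group_totals.add_prefix("total: "))
        joined.to_csv(path)


def evaluate_grid(
    specs: list[AlgorithmSpec],
    datasets: list[DatasetMatrix],
    groups: dict | None = None,
    noise_convention: str = "cluster",
    tune: dict | None = None,
) -> EvaluationTable:
    """Score every spec on every labelled dataset with the V-measure.

    ``tune`` optionally maps an algorithm name to ``(parameter, bounds)``;
    those algorithms are tuned to each dataset's class count before the
    final run. The per-dataset target k defaults to the true class count.
    Per-cell failures are annotated, not raised.
    """
    groups = groups or {}
    names = [s.name for s in specs]
    columns = [d.name for d in datasets]
    scores = pd.DataFrame(np.nan, index=names, columns=columns)
    annotations: dict = {}

    def note(alg, ds, message):
        annotations.setdefault((alg, ds), []).append(message)

    for ds in datasets:
        if ds.labels is None:
            raise ValueError(f"dataset {ds.name!r} has no labels")
        k = ds.n_classes
        for spec in specs:
            cell_spec = spec if spec.target_k is not None else AlgorithmSpec(
                spec.name, spec.params, spec.seed, target_k=k
            )
            try:
                if tune and spec.name in tune:
                    parameter, bounds = tune[spec.name]
                    tuned = tune_to_k(cell_spec, ds, k, parameter, bounds)
                    if not tuned.exact:
                        note(spec.name, ds.name, f"could-not-reach-k ({tuned.achieved_k})")
                    cell_spec = tuned.spec
                result = run(cell_spec, ds)
            except AlgorithmError as exc:
                note(spec.name, ds.name, f"failed: {exc.cause}")
                continue
            noise_fraction = float(np.mean(result.labels == NOISE_LABEL))
            if noise_fraction > EXCESS_NOISE_FRACTION:
                note(spec.name, ds.name, f"excess noise ({noise_fraction:.0%})")
            pred = resolve_noise(result.labels, noise_convention)
            scores.loc[spec.name, ds.name] = v_measure(ds.labels, pred).v

    totals = pd.DataFrame(index=names)
    for group, members in groups.items():
        totals[group] = scores[list(members)].fillna(0.0).sum(axis=1)
    return EvaluationTable(scores=scores, group_totals=totals, annotations=annotations)
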