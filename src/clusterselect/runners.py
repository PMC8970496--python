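"""Uniform execution contract for the fourteen candidate algorithms.

Each adapter takes a preprocessed matrix and returns a flat hard labelling;
fuzzy or probabilistic algorithms return the maximum-membership label, and
density-based algorithms may mark points as noise with the reserved sentinel
(:data:`NOISE_LABEL`), which is preserved for the evaluation stage to handle
explicitly. Identical spec + data + seed always yields identical labels.

Algorithms with established implementations are delegated to scikit-learn;
PAM (k-medoids by Voronoi iteration) and Fuzzy C-Means are implemented here.
:func:`tune_to_k` adjusts a count-controlling hyperparameter (radius,
bandwidth, minimum cluster size, ...) by bisection so algorithms without an
explicit k can be compared at the same cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn import cluster as skcluster
from sklearn.mixture import GaussianMixture

from .dataset import DatasetMatrix

#: Sentinel for points an algorithm left unassigned (noise).
NOISE_LABEL = -1


@dataclass(frozen=True)
class AlgorithmSpec:
    """A named algorithm plus hyperparameters, seed and target cluster count."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    target_k: int | None = None

    def with_params(self, **params) -> "AlgorithmSpec":
        merged = {**self.params, **params}
        return replace(self, params=merged)


@dataclass
class RunResult:
    """Hard labelling produced by one run."""

    labels: np.ndarray
    n_clusters_found: int
    spec: AlgorithmSpec


class AlgorithmError(RuntimeError):
    """An algorithm failed; carries the spec for diagnosis."""

    def __init__(self, spec: AlgorithmSpec, cause: Exception):
        super().__init__(f"{spec.name} failed with {spec.params}: {cause}")
        self.spec = spec
        self.cause = cause


# --------------------------------------------------------------------------
# hand-rolled algorithms (no installed implementation available)


def pam_kmedoids(
    X: np.ndarray, k: int, seed: int = 0, max_iter: int = 300
) -> np.ndarray:
    """Partitioning Around Medoids via Voronoi iteration.

    Greedy (BUILD-style) initialisation from a seeded random start, then
    alternate assignment to the nearest medoid and per-cluster medoid
    update until the medoid set is stable.
    """
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    dist = cdist(X, X)
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d_near)))  # farthest-point seeding
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for ci in range(k):
            members = np.flatnonzero(assign == ci)
            if members.size:
                within = dist[np.ix_(members, members)].sum(axis=1)
                new_medoids[ci] = members[int(np.argmin(within))]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


def fuzzy_c_means(
    X: np.ndarray,
    k: int,
    m: float = 2.0,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
):
    """Fuzzy C-Means: returns (centers, memberships).

    Memberships are initialised from a seeded Dirichlet-like draw; centers
    and memberships alternate until the membership change falls below tol.
    """
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n, k))
    u /= u.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d = cdist(X, centers)
        d = np.fmax(d, 1e-12)
        inv = d ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    return centers, u


# --------------------------------------------------------------------------
# adapters, registered by KB name


def _k(spec: AlgorithmSpec) -> int:
    k = spec.params.get("k", spec.target_k)
    if k is None:
        raise ValueError(f"{spec.name} needs a target cluster count (target_k)")
    return int(k)


def _run_ward(spec, X):
    return skcluster.AgglomerativeClustering(n_clusters=_k(spec), linkage="ward").fit_predict(X)


def _run_single(spec, X):
    return skcluster.AgglomerativeClustering(n_clusters=_k(spec), linkage="single").fit_predict(X)


def _run_birch(spec, X):
    kw = {p: spec.params[p] for p in ("threshold", "branching_factor") if p in spec.params}
    return skcluster.Birch(n_clusters=_k(spec), **kw).fit_predict(X)


def _run_kmeans(spec, X):
    return skcluster.KMeans(
        n_clusters=_k(spec), random_state=spec.seed, n_init=10
    ).fit_predict(X)


def _run_minibatch(spec, X):
    kw = {"batch_size": spec.params.get("batch_size", 1024)}
    return skcluster.MiniBatchKMeans(
        n_clusters=_k(spec), random_state=spec.seed, n_init=10, **kw
    ).fit_predict(X)


def _run_pam(spec, X):
    return pam_kmedoids(X, _k(spec), seed=spec.seed)


def _run_fcm(spec, X):
    _, u = fuzzy_c_means(X, _k(spec), m=spec.params.get("m", 2.0), seed=spec.seed)
    return np.argmax(u, axis=1)


def _run_dbscan(spec, X):
    return skcluster.DBSCAN(
        eps=spec.params.get("eps", 0.5), min_samples=spec.params.get("min_samples", 5)
    ).fit_predict(X)


def _run_hdbscan(spec, X):
    return skcluster.HDBSCAN(
        min_cluster_size=int(spec.params.get("min_cluster_size", 5)),
        min_samples=spec.params.get("min_samples"),
        copy=True,
    ).fit_predict(X)


def _run_optics(spec, X):
    kw = {}
    if "xi" in spec.params:
        kw["xi"] = spec.params["xi"]
    return skcluster.OPTICS(
        min_samples=int(spec.params.get("min_samples", 5)), **kw
    ).fit_predict(X)


def _run_meanshift(spec, X):
    return skcluster.MeanShift(bandwidth=spec.params.get("bandwidth")).fit_predict(X)


def _run_spectral(spec, X):
    kw = {}
    if "gamma" in spec.params:
        kw["gamma"] = spec.params["gamma"]
    return skcluster.SpectralClustering(
        n_clusters=_k(spec), random_state=spec.seed, assign_labels="discretize", **kw
    ).fit_predict(X)


def _run_affinity(spec, X):
    return skcluster.AffinityPropagation(
        damping=spec.params.get("damping", 0.5),
        preference=spec.params.get("preference"),
        random_state=spec.seed,
    ).fit_predict(X)


def _run_gmm(spec, X):
    gm = GaussianMixture(
        n_components=_k(spec),
        covariance_type=spec.params.get("covariance_type", "full"),
        random_state=spec.seed,
        n_init=spec.params.get("n_init", 5),
        reg_covar=spec.params.get("reg_covar", 1e-6),
    ).fit(X)
    return gm.predict(X)  # maximum-posterior hard labels


REGISTRY = {
    "Hierarchical (Ward's)": _run_ward,
    "Hierarchical (Single Link)": _run_single,
    "BIRCH": _run_birch,
    "k-means": _run_kmeans,
    "k-means minibatch": _run_minibatch,
    "PAM": _run_pam,
    "Fuzzy C-Means": _run_fcm,
    "DBSCAN": _run_dbscan,
    "HDBSCAN": _run_hdbscan,
    "OPTICS": _run_optics,
    "Mean Shift": _run_meanshift,
    "Spectral Clustering": _run_spectral,
    "Affinity Propagation": _run_affinity,
    "Gaussian Mixture Model": _run_gmm,
}


def run(spec: AlgorithmSpec, m: DatasetMatrix) -> RunResult:
    """Execute one algorithm under the uniform contract."""
    try:
        adapter = REGISTRY[spec.name]
    except KeyError:
        raise KeyError(
            f"unknown algorithm {spec.name!r}; registered: {sorted(REGISTRY)}"
        )
    try:
        labels = np.asarray(adapter(spec, m.values), dtype=int)
    except Exception as exc:  # propagate with context
        raise AlgorithmError(spec, exc) from exc
    n_found = len(set(labels[labels != NOISE_LABEL]))
    return RunResult(labels=labels, n_clusters_found=n_found, spec=spec)


# --------------------------------------------------------------------------
# tuning a hyperparameter to hit a target cluster count


@dataclass
class TuneResult:
    """Outcome of :func:`tune_to_k`: the tuned spec and whether k was hit."""

    spec: AlgorithmSpec
    achieved_k: int
    exact: bool
    evaluations: int


def tune_to_k(
    spec: AlgorithmSpec,
    m: DatasetMatrix,
    k: int,
    tunable: str,
    bounds: tuple,
    max_evals: int = 60,
    grid_points: int = 64,
) -> TuneResult:
    """Find a value of ``tunable`` whose run yields exactly k clusters.

    Assumes the cluster count responds monotonically to the parameter over
    the bounds and bisects; when the endpoints do not bracket k (or the
    response is locally non-monotone) it falls back to a uniform grid scan
    and returns the closest achievable count, flagged inexact. The returned
    spec is never worse (farther from k) than the input spec.
    """
    if not 1 <= k <= m.n_samples:
        raise ValueError(f"k must be in [1, {m.n_samples}], got {k}")
    evals = 0

    def count_at(value) -> int:
        nonlocal evals
        evals += 1
        return run(spec.with_params(**{tunable: value}), m).n_clusters_found

    best_value, best_count = None, None

    def consider(value, count):
        nonlocal best_value, best_count
        if best_count is None or abs(count - k) < abs(best_count - k):
            best_value, best_count = value, count

    if tunable in spec.params:
        consider(spec.params[tunable], count_at(spec.params[tunable]))
        if best_count == k:
            return TuneResult(spec, k, True, evals)

    lo, hi = float(bounds[0]), float(bounds[1])
    c_lo, c_hi = count_at(lo), count_at(hi)
    consider(lo, c_lo)
    consider(hi, c_hi)

    if best_count != k and min(c_lo, c_hi) <= k <= max(c_lo, c_hi) and c_lo != c_hi:
        increasing = c_hi > c_lo
        a, b = lo, hi
        while evals < max_evals and best_count != k:
            mid = 0.5 * (a + b)
            c_mid = count_at(mid)
            consider(mid, c_mid)
            if c_mid == k:
                break
            if (c_mid < k) == increasing:
                a = mid
            else:
                b = mid

    if best_count != k:  # non-monotone or out-of-range: uniform grid scan
        for value in np.linspace(lo, hi, grid_points):
            consider(value, count_at(float(value)))
            if best_count == k:
                break

    tuned = spec.with_params(**{tunable: best_value})
    return TuneResult(tuned, best_count, best_count == k, evals)
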