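"""Labelled synthetic data with controllable cluster characteristics.

Two generators cover the study's needs: Gaussian cluster layouts
(:func:`make_clusters`) with per-cluster anisotropy, density scaling,
singleton clusters and uniform-box outliers; and spectra-like data
(:func:`make_spectra`) where each class has a Gaussian-peak template
distorted by multiplicative scatter, a polynomial baseline and white noise —
exactly the effects EMSC is designed to remove.

Four archetype presets mirror the shapes and qualitative cluster structure
of the validation dataset families: small unbalanced spectroscopy with
singletons and varying density; balanced overlapping laboratory
spectroscopy; very-high-dimensional balanced spherical expression-like data;
and low-dimensional, well-behaved teaching data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import DatasetMatrix, OUTLIER_LABEL


@dataclass
class ClusterSpec:
    """Gaussian cluster layout.

    sizes / means / covariances:
        One entry per cluster. A covariance may be a full SPD matrix, a
        per-dimension variance vector, or a scalar (isotropic).
    density_scales:
        Per-cluster linear scale factor on point spacing (the covariance is
        multiplied by its square), so a scale ratio of s yields a measured
        nearest-neighbour-distance ratio of about s.
    n_singletons:
        Extra size-1 clusters placed on a shell well outside the main
        layout, each its own class.
    n_outliers / outlier_spread:
        Points drawn uniformly in the data's bounding box inflated by the
        spread factor, labelled with the reserved outlier label.
    """

    sizes: list
    means: list
    covariances: list
    density_scales: list | None = None
    n_singletons: int = 0
    n_outliers: int = 0
    outlier_spread: float = 3.0
    seed: int = 0

    @property
    def n_features(self) -> int:
        return len(np.atleast_1d(self.means[0]))


@dataclass
class SpectraSpec:
    """Spectra-like data: per-class peak templates plus measurement effects.

    templates:
        One list of peaks per class; a peak is (position, width, height) on
        the wavenumber grid.
    baseline_ranges:
        Per-degree coefficient ranges (lo, hi) for the additive polynomial
        baseline, sampled per spectrum on the grid rescaled to [-1, 1].
    scatter_range:
        Range of the per-spectrum multiplicative scatter factor.
    noise_sd:
        White-noise standard deviation; a scalar, or one value per class
        (which makes within-class spread vary between classes).
    """

    wavenumbers: np.ndarray
    templates: list
    class_sizes: list
    baseline_ranges: list = field(default_factory=list)
    scatter_range: tuple = (1.0, 1.0)
    noise_sd: float | list = 0.0
    seed: int = 0

    def template_matrix(self) -> np.ndarray:
        """Class templates evaluated on the grid (n_classes x n_features)."""
        grid = np.asarray(self.wavenumbers, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        out = np.zeros((len(self.templates), grid.size))
        for ci, peaks in enumerate(self.templates):
            for pos, width, height in peaks:
                out[ci] += height * np.exp(-0.5 * ((grid - pos) / width) ** 2)
        return out


def _as_cov(cov, dim: int) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0:
        cov = np.eye(dim) * float(cov)
    elif cov.ndim == 1:
        cov = np.diag(cov)
    if cov.shape != (dim, dim):
        raise ValueError(f"covariance shape {cov.shape} does not match dim {dim}")
    return cov


def make_clusters(spec: ClusterSpec) -> DatasetMatrix:
    """Draw the Gaussian cluster layout; deterministic given the seed."""
    if len(spec.sizes) != len(spec.means) or len(spec.sizes) != len(spec.covariances):
        raise ValueError("sizes, means and covariances must align")
    if any(s < 1 for s in spec.sizes):
        raise ValueError("cluster sizes must be >= 1")
    rng = np.random.default_rng(spec.seed)
    dim = spec.n_features
    scales = spec.density_scales or [1.0] * len(spec.sizes)

    points, labels = [], []
    for ci, (size, mean, cov, scale) in enumerate(
        zip(spec.sizes, spec.means, spec.covariances, scales)
    ):
        cov = _as_cov(cov, dim) * scale**2
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(f"cluster {ci}: covariance is not positive definite")
        draws = rng.standard_normal((size, dim)) @ chol.T + np.atleast_1d(mean)
        points.append(draws)
        labels.append(np.full(size, ci))

    body = np.vstack(points)
    next_label = len(spec.sizes)

    # singleton clusters on a shell outside the main layout
    if spec.n_singletons:
        centre = body.mean(axis=0)
        radius = 2.0 * np.max(np.linalg.norm(body - centre, axis=1))
        for _ in range(spec.n_singletons):
            direction = rng.standard_normal(dim)
            direction /= np.linalg.norm(direction)
            points.append((centre + radius * direction)[None, :])
            labels.append(np.array([next_label]))
            next_label += 1
        body = np.vstack(points)

    if spec.n_outliers:
        lo, hi = body.min(axis=0), body.max(axis=0)
        mid, half = (lo + hi) / 2, (hi - lo) / 2
        lo = mid - half * spec.outlier_spread
        hi = mid + half * spec.outlier_spread
        points.append(rng.uniform(lo, hi, size=(spec.n_outliers, dim)))
        labels.append(np.full(spec.n_outliers, OUTLIER_LABEL))

    return DatasetMatrix(
        values=np.vstack(points), labels=np.concatenate(labels), name="synthetic-clusters"
    )


def make_spectra(spec: SpectraSpec) -> DatasetMatrix:
    """Generate spectra: scatter · template + baseline polynomial + noise."""
    if len(spec.class_sizes) != len(spec.templates):
        raise ValueError("class_sizes and templates must align")
    if any(s < 1 for s in spec.class_sizes):
        raise ValueError("every class needs at least one spectrum")
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.wavenumbers, dtype=float)
    templates = spec.template_matrix()
    lam = 2.0 * (grid - grid.min()) / (grid.max() - grid.min()) - 1.0
    noise_sds = (
        list(spec.noise_sd)
        if np.ndim(spec.noise_sd) > 0
        else [float(spec.noise_sd)] * len(spec.class_sizes)
    )

    rows, labels = [], []
    for ci, size in enumerate(spec.class_sizes):
        scatter = rng.uniform(*spec.scatter_range, size=size)
        sample = scatter[:, None] * templates[ci]
        for degree, (lo, hi) in enumerate(spec.baseline_ranges):
            coef = rng.uniform(lo, hi, size=size)
            sample = sample + coef[:, None] * lam**degree
        sample = sample + rng.standard_normal(sample.shape) * noise_sds[ci]
        rows.append(sample)
        labels.append(np.full(size, ci))
    return DatasetMatrix(
        values=np.vstack(rows),
        labels=np.concatenate(labels),
        axis=grid,
        name="synthetic-spectra",
    )


def _spread_peaks(rng: np.random.Generator, grid, n_peaks: int) -> list:
    lo, hi = grid.min(), grid.max()
    span = hi - lo
    positions = rng.uniform(lo + 0.05 * span, hi - 0.05 * span, size=n_peaks)
    widths = rng.uniform(0.01 * span, 0.03 * span, size=n_peaks)
    heights = rng.uniform(0.3, 1.0, size=n_peaks)
    return list(zip(positions, widths, heights))


def archetype_presets(seed: int = 0, gene_features: int = 20531) -> dict:
    """Specs mirroring the four validation dataset archetypes.

    ``gene_features`` can be lowered to subsample the expression-like
    preset's feature width for fast runs; the cluster structure is
    unaffected.
    """
    rng = np.random.default_rng(seed)

    # explosives_like: FTIR-shaped (3350 points), 7 unbalanced classes
    # incl. a singleton, per-class noise levels giving varying density.
    # Related materials share common absorption bands, so templates are a
    # shared backbone plus class-specific peaks.
    grid = np.linspace(600.0, 3950.0, 3350)
    backbone = _spread_peaks(rng, grid, 6)
    explosives = SpectraSpec(
        wavenumbers=grid,
        templates=[backbone + _spread_peaks(rng, grid, 4) for _ in range(7)],
        class_sizes=[25, 18, 12, 8, 5, 4, 1],
        baseline_ranges=[(-0.3, 0.3), (-0.2, 0.2), (-0.1, 0.1)],
        scatter_range=(0.7, 1.3),
        noise_sd=[0.005, 0.005, 0.02, 0.005, 0.02, 0.005, 0.005],
        seed=seed,
    )

    # public_like: balanced classes, a few hundred points, overlapping
    # templates (shared peaks + small class-specific differences)
    grid_p = np.linspace(900.0, 1800.0, 300)
    shared = _spread_peaks(rng, grid_p, 6)
    public_templates = []
    for _ in range(4):
        own = _spread_peaks(rng, grid_p, 2)
        public_templates.append(shared + [(p, w, 0.3 * h) for p, w, h in own])
    public = SpectraSpec(
        wavenumbers=grid_p,
        templates=public_templates,
        class_sizes=[30, 30, 30, 30],
        baseline_ranges=[(-0.2, 0.2), (-0.1, 0.1)],
        scatter_range=(0.85, 1.15),
        noise_sd=0.02,
        seed=seed + 1,
    )

    # gene_like: 801 x 20531-shaped, 5 balanced spherical classes
    k, dim = 5, gene_features
    gene_means = rng.standard_normal((k, dim)) * 1.2
    gene = ClusterSpec(
        sizes=[161, 160, 160, 160, 160],
        means=list(gene_means),
        covariances=[1.0] * k,
        seed=seed + 2,
    )

    # classic_like: low-dimensional, balanced, well separated
    classic = ClusterSpec(
        sizes=[50, 50, 50],
        means=[np.zeros(4), np.full(4, 6.0), np.array([6.0, -6.0, 6.0, -6.0])],
        covariances=[1.0, 1.0, 1.0],
        seed=seed + 3,
    )

    return {
        "explosives_like": explosives,
        "public_like": public,
        "gene_like": gene,
        "classic_like": classic,
    }


def get_archetype(name: str, seed: int = 0, **kwargs) -> DatasetMatrix:
    """Generate one archetype dataset by name."""
    presets = archetype_presets(seed=seed, **kwargs)
    try:
        spec = presets[name]
    except KeyError:
        raise KeyError(f"unknown archetype {name!r}; available: {sorted(presets)}")
    data = make_spectra(spec) if isinstance(spec, SpectraSpec) else make_clusters(spec)
    return data.replace(name=name)
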