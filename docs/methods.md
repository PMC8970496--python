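# Methods

## The selection model

The package treats clustering-algorithm choice as a matching problem
between three profiles: what the *data* is like, what the *clusters* in it
are like, and what the *analysis context* demands. Eleven evaluation
characteristics carry that information:

| source | characteristics |
|---|---|
| dataset | small_datasets, high_dimensions |
| cluster structure | non_spherical_shape, variable_cluster_density, single_point_cluster, uneven_cluster_size, robust_noise_outliers |
| algorithm/context | multimodal_hierarchical, parameter_simplicity, deterministic, efficiency |

The knowledge base (`data/table3.yaml`) profiles fourteen widely used
algorithms — two agglomerative linkages, BIRCH, k-means and its minibatch
variant, PAM, fuzzy c-means, DBSCAN, HDBSCAN, OPTICS, mean shift, spectral
clustering, affinity propagation and Gaussian mixtures — against these
characteristics with yes/no/unknown cells. `unknown` records a genuine
information gap and is never treated as `no`: it contributes nothing to a
match score but is surfaced in every report, so a user can decide whether
the gap matters enough to research.

Matching is a weighted count: each required characteristic contributes its
weight (default 1) when the profile says `yes`; characteristics of minor
consideration default to weight 0.5. The majority rule keeps algorithms
scoring strictly more than half the attainable weight; top-m and threshold
rules are available when the caller wants a fixed-size or calibrated cut.
Ties in the ranking are broken by knowledge-base row order, which makes
every selection reproducible. Hard constraints bypass scoring entirely:
`k_only` keeps algorithms whose single user-facing parameter is the cluster
count, and `max_complexity` cuts on a total "growth order in n" ranking

    n < n log n < n·k·d·i < n² < n²·i < n² log n < n³

in which k (clusters), d (dimensions) and i (iterations) are treated as
data-independent factors. Affinity propagation is encoded as n²·i — its
message-passing iterations put it strictly above a plain n² bound — with a
caveat string recording that its complexity is commonly printed as n².
The soft/hard split is deliberate: `efficiency` may never be a soft
requirement (a complexity class is not a yes/no support), and
`parameter_simplicity` is accepted only at minor weight, where a profile
satisfies it iff it is k-only; at full weight it must be expressed as the
`hard_k_only` constraint instead, so that "easy to use" never silently
outvotes structural fit.

Four requirement presets encode the validation scenarios: forensic
explosives spectroscopy (seven structural requirements, parameter count and
determinism at minor weight — the analysis may be automated), laboratory
spectroscopy (six requirements, no minor terms), gene expression (high
dimensions with a hard n² efficiency cap) and classic teaching data (the
single hard constraint of requiring only k). The majority rule admits, for
the two spectroscopy scenarios, a few algorithms beyond the ones the
original study chose; the study's final cut involved analyst judgement that
no scoring rule reproduces, so the engine reports the full ranking and
leaves the final say to the caller.

## Characterization

Cluster-structure measures assume a labelled matrix (true labels, or
provisional labels from Ward linkage at a user-supplied k, flagged
`estimated`):

- **balance_ratio** = min/max cluster size; *uneven* below 0.5.
- **single-point cluster**: any class of size 1. Distinct from outliers:
  a singleton is a real class a good algorithm should isolate.
- **density_variation_ratio** = max/min of per-cluster mean
  nearest-neighbour distance (full feature space; size-1 clusters carry no
  density information and are excluded); *variable* above 2.
- **max_elongation** = max over clusters of √(λ₁/λ₂) of the within-cluster
  covariance in the 2-component PCA projection; *non-spherical* above 2.
  The projection mirrors how an analyst reads a PC1/PC2 score plot; it can
  understate elongation that lives outside the first two components.
- **outlier_fraction**: points whose within-cluster nearest-neighbour
  distance exceeds the cluster median by more than 10 normal-consistent
  MADs (MAD × 1.4826), plus points carrying the reserved outlier label
  (−1); *noise/outliers present* above 2%. The multiplier is deliberately
  large: nearest-neighbour distances are heavy-tailed even in clean
  Gaussian clusters (the periphery is always sparse), and at 3 MADs the
  rule flags 7–17% of clean Gaussian points, which would mark every
  dataset as noisy. At 10 MADs no clean-cluster point is flagged across 30
  seeds while detached points are still caught.

Size thresholds: *small* below 1000 samples, *high-dimensional* above 50
features. All thresholds live in one config object (`Thresholds`); the
source framework describes every one of these characteristics only
qualitatively, so the defaults are operationalizations chosen to agree
with its qualitative judgements, not published values.

PCA is centred but never scaled (scaling is a preprocessing decision);
explained fractions are per-axis shares of total variance.

## EMSC

For spectra with a wavenumber axis, each sample x is fitted by ordinary
least squares to

    x ≈ a·1 + b·m + Σⱼ dⱼ·λʲ (j = 1..order) + Σₖ gₖ·qₖ

with m a reference spectrum (dataset mean by default), λ the wavenumber
axis rescaled to [−1, 1] for conditioning, and qₖ optional interferent
spectra. The corrected spectrum is (x − a − Σdⱼλʲ − Σgₖqₖ)/b. Polynomial
order defaults to 2 (offset, slope, curvature). The design matrix is built
once for the whole dataset and solved for all spectra in a single lstsq
call; a rank-deficient design (e.g. an interferent inside the polynomial
span) is an error. Spectra with |b| below 1e-8 are flagged degenerate and
passed through uncorrected rather than amplified by a near-zero division.
Correction is exact (machine precision) for any spectrum inside the design
span, and a second pass with the same model is the identity. The specific
EMSC configuration used in the source study is not recorded (it was run
through an external toolbox); the defaults here are standard chemometric
practice.

## Runners and tuning

Adapters execute each algorithm behind one contract: a hard label vector,
noise marked with −1 and preserved for the evaluation stage, and identical
labels for identical spec + data + seed. Twelve algorithms delegate to
scikit-learn (including HDBSCAN, available there since 1.3); PAM
(k-medoids via farthest-point seeding and Voronoi iteration) and fuzzy
c-means (m = 2, membership argmax for hard labels) are implemented in
`runners.py` because no installed library provides them. Algorithms whose
cluster count is indirect (radius, bandwidth, minimum cluster size) are
brought to a target k by bisection on the controlling parameter (≤ 60
evaluations, assuming monotone response), with a 64-point grid-scan
fallback for non-monotone regions; an unreachable k is returned as the
closest achievable count with an explicit `exact=False` flag, never as a
silent success.

## Evaluation

Homogeneity, completeness and V are computed from the class × cluster
contingency table with natural-log entropies (all three are entropy
ratios, so the base cancels), with the standard conventions h = 1 when
H(C) = 0, c = 1 when H(K) = 0, and V = 0 when βh + c = 0. β defaults to 1.
scikit-learn's implementation is used only as an independent cross-check
in the tests.

Noise points require a convention before external scoring: by default all
noise becomes one extra cluster (so abundant noise costs homogeneity); the
alternative maps each noise point to its own singleton cluster (costing
completeness instead). The choice is a visible parameter because the two
conventions can differ materially when noise is plentiful, and grid cells
with more than 25% noise are annotated.

Internal indices: mean silhouette and Davies–Bouldin delegate to
scikit-learn (with explicit precondition checks — at least two clusters,
non-coincident centroids); the Dunn index (minimum single-linkage
inter-cluster distance over maximum intra-cluster diameter) is computed
directly from the pairwise distance matrix.

The evaluation grid records a V-measure per (algorithm, dataset) cell,
appends per-group totals (plain row sums over each group's columns), and
degrades per-cell failures to annotations instead of aborting the grid.

## Synthetic data

`make_clusters` draws Gaussian clusters with per-cluster anisotropy and a
linear density scale (covariance multiplied by scale², so a scale ratio s
appears as a nearest-neighbour distance ratio ≈ s), places optional
singleton classes on a shell at twice the layout's radius, and scatters
optional outliers uniformly in a 3×-inflated bounding box with the
reserved label −1. `make_spectra` builds per-class templates as sums of
Gaussian peaks and distorts every sample with a multiplicative scatter
factor, a random polynomial baseline and white noise — exactly the effects
EMSC models. Everything is deterministic given the seed.

The four archetype presets mirror the shapes and qualitative structure of
the validation families: `explosives_like` (73 × 3350 spectra, seven
classes sized 25…1 including a singleton, per-class noise levels giving
density variation; templates share a common backbone of bands plus
class-specific peaks, as related materials do — fully independent random
templates would let a class be near-orthogonal to the mean reference and
make EMSC's multiplicative fit degenerate, which is not a failure mode of
real spectra of related compounds), `public_like` (4 × 30 balanced,
overlapping templates, 300 points), `gene_like` (801 samples, 20531
features, five balanced spherical classes; the feature width can be
subsampled for fast runs without changing the cluster structure) and
`classic_like` (150 × 4, three balanced separated blobs). The generators
emulate cluster *structure*, not instrument physics: no detector
nonlinearity, wavelength misalignment, correlated noise, or non-Gaussian
class shapes. Passing tests therefore demonstrate that the measures and
the pipeline behave correctly on data with known structure, not that any
particular real dataset has that structure.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: structure
recovery and EMSC variance-reduction properties use 20 seeds at 80–120
samples; the full-width gene-like preset is exercised structurally (shape
metadata) with clustering checks on a feature-subsampled draw; the
benchmark checks on iris (150 × 4) and wine (178 × 13) use the copies
packaged with scikit-learn. Stochastic algorithm benchmarks average 10
seeds. Degenerate inputs are defined errors, not silent results: empty
matrices, q beyond the rank, a single cluster for internal indices,
all-singleton clusterings for Dunn, coincident centroids for
Davies–Bouldin.

One reproduction note: the source study reports that multivariate data was
scaled and centred, but its published iris V-measures (Ward 0.77, k-means
0.76, GMM 0.90) are only reproduced on the raw features — standardized
iris gives Ward ≈ 0.675 — while its wine values (0.79 / 0.89 / 0.88) are
reproduced on standardized features (raw gives Ward ≈ 0.416). The
benchmark tests therefore run iris unscaled and wine standardized, and the
per-algorithm hyperparameters of the original runs (recorded only in
supplementary material) are taken as library defaults plus the true k.

## Known limitations

- The knowledge base is a faithful encoding of its source matrix,
  including cells one might dispute (minibatch k-means marked unsuitable
  for small datasets; OPTICS's efficiency printed as n); it is not a
  curated review of the clustering literature.
- Elongation in the 2-component projection can miss anisotropy orthogonal
  to the leading components; a full-space measure would need a different
  sphericity statistic.
- The majority rule reports more candidates than a human analyst might
  keep (see the scenario discussion above); exact set reproduction is
  only guaranteed where the published cut was purely mechanical (the
  gene-expression and classic-ML scenarios).
- Cluster-count prediction (elbow, gap statistic) is out of scope; the
  target k is always supplied by the caller.
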