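# clusterselect

Tools for choosing a clustering algorithm that fits both the data and the
analyst's needs — built around spectroscopy (FTIR/NIR/MIR) and other
tabular scientific data such as gene-expression matrices.

There is no universally best clustering algorithm: performance depends on
the cluster structure of the data (balance, density, shape, singletons,
noise) and on practical needs the data cannot express (hierarchical output,
parameter simplicity, determinism, computational cost). `clusterselect`
makes that trade-off explicit as a four-stage workflow:

1. **Characterize** (`characterize`) — measure dataset characteristics
   (size, dimensionality) and cluster-structure characteristics from a
   labelled or provisionally clustered matrix: balance ratio min/max,
   single-point clusters, per-cluster nearest-neighbour density variation,
   elongation √(λ₁/λ₂) in the 2-component PCA projection, and an outlier
   fraction.
2. **State requirements** (`select.RequirementSet`) — the characteristics
   that matter for the application, with full or minor weight, plus hard
   constraints (k-only parameterization, a time-complexity cap).
3. **Down-select** (`select`) — score all fourteen profiled algorithms in
   the shipped knowledge base (`kb`, a comparative matrix of yes/no/unknown
   support over eleven characteristics) and keep those above half the
   attainable weighted score, or the top-m, or a threshold.
4. **Evaluate** (`evaluate`) — run the survivors under a uniform contract
   (`runners`) and rank them with the V-measure

   V_β = (1+β)·h·c / (β·h + c),  h = 1 − H(C|K)/H(C),  c = 1 − H(K|C)/H(K)

   (β = 1 by default: the harmonic mean of homogeneity and completeness),
   or with label-free internal indices (silhouette, Davies–Bouldin, Dunn).

Spectra are preprocessed with extended multiplicative signal correction
(EMSC, `preprocess`): each spectrum is regressed on a reference spectrum
plus wavenumber polynomials, removing additive baseline, multiplicative
scatter and optional interferent contributions. Plain multivariate data is
centred and scaled. A synthetic-data module (`synth`) generates labelled
cluster layouts and spectra with controllable characteristics, including
four archetype presets that mirror the validation dataset families.

## Worked example

```python
import clusterselect as cs

kb = cs.load_kb()                       # 14 algorithm profiles
req = cs.get_preset("gene_expression")  # high dimensions + efficiency <= n^2
result = cs.select(kb, req)
print(result.selected)
# ['BIRCH', 'k-means minibatch']

report = cs.run_pipeline(cs.PipelineConfig(
    data="classic_like", preprocessing="standardize",
    requirements="classic_ml", seed=0,
))
print(report.selection.selected)
# ["Hierarchical (Ward's)", 'Hierarchical (Single Link)', 'k-means',
#  'PAM', 'Fuzzy C-Means', 'Gaussian Mixture Model']
print(report.evaluation.scores)
#                             classic_like
# Hierarchical (Ward's)                1.0
# Hierarchical (Single Link)           1.0
# k-means                              1.0
# PAM                                  1.0
# Fuzzy C-Means                        1.0
# Gaussian Mixture Model               1.0
```

The teaching-data scenario's single need is ease of use, so the hard
constraint keeps exactly the six algorithms whose only parameter is the
cluster count k; on the well-separated synthetic blobs every one of them
recovers the true labelling, so all tie at V = 1.0.

The `examples/` directory holds one short script per capability
(characterization, down-selection, EMSC, validity indices, full pipeline);
each builds a small input, runs the method, and prints what the numbers
mean. A thin CLI mirrors the stages:

```bash
clusterselect select --requirements gene_expression
clusterselect run --data classic_like --requirements classic_ml \
    --preprocess standardize --seed 0 --out report/
```

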