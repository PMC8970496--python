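# Default algorithm knowledge base: the comparative matrix of fourteen
# candidate clustering algorithms against the eleven evaluation
# characteristics. Blank cells in the source matrix are encoded as
# "unknown" (an information gap, distinct from "no"); footnoted
# qualifiers are carried as caveat text on the affected cell.
- name: "Hierarchical (Ward's)"
  family: hierarchical
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "no"
    variable_cluster_density: "yes"
    single_point_cluster: "yes"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "yes"
    multimodal_hierarchical: "yes"
  parameters: [k]
  deterministic: "yes"
  complexity: "n^2 log n"

- name: "Hierarchical (Single Link)"
  family: hierarchical
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "yes"
    variable_cluster_density: "no"
    single_point_cluster: "yes"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "no"
    multimodal_hierarchical: "yes"
  parameters: [k]
  deterministic: "yes"
  complexity: "n^2 log n"

- name: "BIRCH"
  family: hierarchical
  support:
    small_datasets: "yes"
    high_dimensions: "yes"
    non_spherical_shape: "no"
    variable_cluster_density: "unknown"
    single_point_cluster: "yes"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "yes"
    multimodal_hierarchical: "yes"
  parameters: [k, threshold, branching_factor]
  deterministic: "unknown"
  complexity: "n"

- name: "k-means"
  family: partition
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "no"
    variable_cluster_density: "no"
    single_point_cluster: "yes"
    uneven_cluster_size: "no"
    robust_noise_outliers: "no"
    multimodal_hierarchical: "no"
  parameters: [k]
  deterministic: "no"
  complexity: "n k d i"

- name: "k-means minibatch"
  family: partition
  support:
    small_datasets: "no"
    high_dimensions: "yes"
    non_spherical_shape: "no"
    variable_cluster_density: "no"
    single_point_cluster: "yes"
    uneven_cluster_size: "no"
    robust_noise_outliers: "no"
    multimodal_hierarchical: "no"
  parameters: [k, batch_size]
  deterministic: "no"
  complexity: "n k d i"
  complexity_caveat: "sub-linear factor relative to k-means (printed < n k d i)"

- name: "PAM"
  family: partition
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "no"
    variable_cluster_density: "no"
    single_point_cluster: "yes"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "yes"
    multimodal_hierarchical: "no"
  parameters: [k]
  deterministic: "no"
  complexity: "n^2 k^2"

- name: "Fuzzy C-Means"
  family: partition
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "no"
    variable_cluster_density: "unknown"
    single_point_cluster: "yes"
    uneven_cluster_size: "no"
    robust_noise_outliers: "no"
    multimodal_hierarchical: "no"
  parameters: [k]
  deterministic: "no"
  complexity: "n k^2 d i"

- name: "DBSCAN"
  family: density
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "yes"
    variable_cluster_density: "no"
    single_point_cluster:
      level: "yes"
      caveat: "enabling single-point clusters removes outlier/noise detection"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "yes"
    multimodal_hierarchical: "no"
  parameters: [eps, min_samples]
  deterministic:
    level: "yes"
    caveat: "results can change with the order the data is provided"
  complexity: "n log n"

- name: "HDBSCAN"
  family: density
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "yes"
    variable_cluster_density: "yes"
    single_point_cluster:
      level: "yes"
      caveat: "enabling single-point clusters removes outlier/noise detection"
    uneven_cluster_size: "unknown"
    robust_noise_outliers: "yes"
    multimodal_hierarchical:
      level: "yes"
      caveat: "hierarchy inferable from the condensed-tree output"
  parameters: [min_cluster_size, min_samples]
  deterministic: "yes"
  complexity: "n^2"

- name: "OPTICS"
  family: density
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "yes"
    variable_cluster_density: "yes"
    single_point_cluster: "no"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "yes"
    multimodal_hierarchical:
      level: "yes"
      caveat: "hierarchy inferable from the reachability ordering"
  parameters: [min_samples, xi]
  deterministic:
    level: "yes"
    caveat: "results can change with the order the data is provided"
  complexity: "n"

- name: "Mean Shift"
  family: density
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "yes"
    variable_cluster_density: "no"
    single_point_cluster: "yes"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "yes"
    multimodal_hierarchical:
      level: "yes"
      caveat: "hierarchy inferable from the mode structure"
  parameters: [bandwidth]
  deterministic: "unknown"
  complexity: "n^2"

- name: "Spectral Clustering"
  family: graph/spectral
  support:
    small_datasets: "no"
    high_dimensions: "yes"
    non_spherical_shape: "yes"
    variable_cluster_density: "unknown"
    single_point_cluster: "yes"
    uneven_cluster_size: "no"
    robust_noise_outliers: "no"
    multimodal_hierarchical: "no"
  parameters: [k, gamma]
  deterministic: "no"
  complexity: "n^3"

- name: "Affinity Propagation"
  family: graph/spectral
  support:
    small_datasets: "yes"
    high_dimensions: "yes"
    non_spherical_shape: "yes"
    variable_cluster_density: "no"
    single_point_cluster: "yes"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "no"
    multimodal_hierarchical:
      level: "yes"
      caveat: "hierarchy inferable from the exemplar structure"
  parameters: [damping, preference]
  deterministic: "unknown"
  complexity: "n^2 i"
  complexity_caveat: >-
    printed as n^2; encoded with the iteration factor of message passing so
    it ranks strictly above n^2, matching its exclusion under an
    efficiency-at-most-n^2 constraint

- name: "Gaussian Mixture Model"
  family: model-based
  support:
    small_datasets: "yes"
    high_dimensions: "no"
    non_spherical_shape: "yes"
    variable_cluster_density: "yes"
    single_point_cluster: "yes"
    uneven_cluster_size: "yes"
    robust_noise_outliers: "yes"
    multimodal_hierarchical: "no"
  parameters: [k]
  deterministic: "no"
  complexity: "n k d^3"
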