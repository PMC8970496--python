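"""Stage 4: score clusterings with external and internal validity indices.

Runs three algorithms on well-separated blobs and one deliberately
mis-parameterized run, then scores each against the ground truth with the
V-measure (1.0 = perfect labelling, 0.0 = uninformative) and with internal
indices that need no labels.
"""

import clusterselect as cs

data = cs.get_archetype("classic_like", seed=0)

for name in ["Hierarchical (Ward's)", "k-means", "Gaussian Mixture Model"]:
    result = cs.run(cs.AlgorithmSpec(name, seed=0, target_k=3), data)
    vm = cs.v_measure(data.labels, result.labels)
    print(f"{name:28s} V = {vm.v:.3f}  (h = {vm.h:.3f}, c = {vm.c:.3f})")

# merging two true clusters: homogeneity drops, completeness stays 1
merged = cs.run(cs.AlgorithmSpec("k-means", seed=0, target_k=2), data)
vm = cs.v_measure(data.labels, merged.labels)
print(f"{'k-means forced to k=2':28s} V = {vm.v:.3f}  (h = {vm.h:.3f}, c = {vm.c:.3f})")

labels = cs.run(cs.AlgorithmSpec("k-means", seed=0, target_k=3), data).labels
print(f"\ninternal indices at k=3 (no ground truth needed):")
print(f"  mean silhouette : {cs.silhouette(data, labels):.3f}   (near 1 = compact, separated)")
print(f"  Davies-Bouldin  : {cs.davies_bouldin(data, labels):.3f}   (lower is better)")
print(f"  Dunn            : {cs.dunn(data, labels):.3f}   (higher is better)")
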