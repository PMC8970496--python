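"""Stage 1: measure what kind of cluster structure a dataset carries.

Generates a small forensic-spectroscopy-like dataset (unbalanced classes,
one single-sample class, per-class density differences) and characterizes
it. The printed flags are the seven data/cluster characteristics that later
drive algorithm selection.
"""

import clusterselect as cs

data = cs.get_archetype("explosives_like", seed=0)
dc = cs.characterize_dataset(data)
st = cs.characterize_clusters(data)

print(f"{data.name}: {dc.n_samples} samples x {dc.n_features} features, "
      f"{dc.n_classes} classes")
print(f"small dataset: {dc.small_dataset}   high-dimensional: {dc.high_dimensional}")
print(f"cluster sizes: {st.sizes.tolist()}  (balance ratio {st.balance_ratio:.3f})")
print(f"density variation ratio: {st.density_variation_ratio:.2f}  "
      f"max elongation: {st.max_elongation:.2f}")
print("derived requirement profile (True = the data exhibits it):")
for characteristic, on in cs.derive_requirement_profile(dc, st).items():
    print(f"  {characteristic.value:28s} {on}")
# A balance ratio far below 0.5 and a singleton class mean this data needs
# algorithms that tolerate uneven and single-point clusters.
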