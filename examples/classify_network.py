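"""Classify a network: level, reticulation arity, blob decomposition.

The level (max reticulations per biconnected component) and the
reticulation arity (max in-degree) decide which exact optimization
algorithm applies.
"""

from netdiv import blobs, classify, random_level_k, write_enewick

net = random_level_k(8, k=2, d=2, seed=42, weights="int:1,9")
print(write_enewick(net))

prof = classify(net)
print(f"level {prof.level}, arity {prof.arity}, "
      f"galled tree: {prof.is_galled_tree}, semibinary: {prof.is_semibinary}")

for b in blobs(net):
    print(f"blob with {len(b.nodes)} nodes: split node {b.split_node}, "
          f"exit reticulations {sorted(b.exit_reticulations)}, "
          f"internal {sorted(b.internal_reticulations) or '-'}")

# A level-2 semibinary network routes to the pooled-candidate greedy;
# a tree (level 0) would use simple best-leaf augmentation.
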