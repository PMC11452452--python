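"""Score leaf subsets of a phylogenetic network with rPSD.

rPSD of a leaf set X is the total weight of every arc with a descendant
in X — on a tree this is Faith's phylogenetic diversity, on a network
it also charges all reticulate ancestry of X.
"""

from netdiv import EXAMPLE1_ENEWICK, read_enewick, rpsd

net = read_enewick(EXAMPLE1_ENEWICK)
print(f"network: {len(net.nodes)} nodes, {len(net.arcs)} arcs, "
      f"total weight {net.total_weight}")

for X in [{"x2"}, {"x2", "x4"}, {"x1", "x3", "x4"}, set(net.leaves)]:
    print(f"rPSD({sorted(X)}) = {rpsd(net, X)}")

# The reticulate leaf x2 inherits from both sides of the gall, so its
# singleton diversity (6) exceeds that of any other single leaf even
# though its pendant branch is the shortest in the network.
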