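"""The strong exchange property fails on networks — richer swaps fix it.

On trees, one can always move a single leaf from the larger of two leaf
sets to the smaller without decreasing the summed diversity.  On the
four-leaf galled tree below this fails, but a two-for-one swap from the
family S_{1,2} succeeds.
"""

from netdiv import SwapFamily, example1_fixture, find_improving_pair, rpsd

net = example1_fixture()
X = frozenset({"x1", "x3", "x4"})
Xp = frozenset({"x2", "x4"})

print(f"rPSD(X) + rPSD(X') = {rpsd(net, X) + rpsd(net, Xp)}")       # 23
for x in sorted(X - Xp):
    moved = rpsd(net, X - {x}) + rpsd(net, Xp | {x})
    print(f"move {x}: {moved}")                                      # 21 each

print("improving pair in S_0:",
      find_improving_pair(net, X, Xp, SwapFamily.s0(net.leaves)))    # None
print("improving pair in S_{1,2}:",
      find_improving_pair(net, X, Xp, SwapFamily.skd(1, 2, net.leaves)))

# ({x1,x3},{x2}): trading the pair x1,x3 for the reticulate leaf x2
# keeps the sum at 23 — exactly the exchange the greedy algorithm needs.
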