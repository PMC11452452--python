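"""Exact maximum-diversity leaf subsets of every size, greedily.

On galled trees every optimal set of size m arises from an optimal set
of size m-1 by optimally adding a leaf or optimally replacing a leaf by
a pair — so the full families Opt_m can be grown greedily and match
brute force exactly.
"""

from netdiv import brute_force_opt, dispatch_optimize, example1_fixture

net = example1_fixture()
seq = dispatch_optimize(net)  # auto-routes to the galled-tree greedy

for fam in seq:
    sets = " ".join("{" + ",".join(sorted(s)) + "}" for s in sorted(fam.sets, key=sorted))
    print(f"m={fam.m}  value={fam.value}  Opt_m = {sets}")
    assert fam.sets == brute_force_opt(net, fam.m).sets

# Note the non-nesting: Opt_2 = {x2,x4} is NOT contained in
# Opt_3 = {x1,x3,x4} — picking leaves one at a time without the
# replace-by-pair move would get stuck at the wrong subset.
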