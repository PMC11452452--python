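"""Probe the open question: does the greedy recursion reach all optima
on semibinary level-3 networks?

No greedy algorithm is proven for semibinary level-3 (or semi-4-ary
level-1) networks.  The gap scan checks, entirely by brute force,
whether every optimal set of size m is an optimal expansion of an
optimal set of size m-j (j <= 3).  A violation certificate would be a
genuine research find; none is known.
"""

from netdiv import classify, gap_scan, random_level_k

for seed in range(5):
    net = random_level_k(7, k=3, d=2, seed=seed, weights="int:1,9")
    report = gap_scan(net, J=3)
    status = "closed" if report.ok else f"VIOLATED: {report.counterexamples}"
    print(f"seed {seed}: level {classify(net).level}, "
          f"optima values {tuple(map(str, report.optima.values))} -> {status}")

# "closed" means every brute-force optimum was reachable by an optimal
# j-step expansion (j <= 3) from a smaller brute-force optimum.
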