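# netdiv — rooted phylogenetic subnet diversity on networks

`netdiv` computes the **rooted Phylogenetic Subnet Diversity** (rPSD,
also known as AllPaths-PD) on weighted rooted phylogenetic networks and
finds **maximum-diversity leaf subsets** of every size, exactly.  It is
aimed at people working on phylogenetic-diversity-based conservation
prioritization and on the combinatorics of phylogenetic networks:
when evolutionary histories contain reticulate events (hybridization,
recombination, lateral transfer), Faith's tree-based PD machinery no
longer applies as-is, and this package implements the network
generalization and its exchange-property-based greedy algorithms.

## The quantity and the problem

A phylogenetic network *N* on a label set Σ is a rooted DAG whose
leaves are bijectively labelled by Σ and in which every node of
in-degree ≥ 2 (a *reticulation*) has out-degree 1.  With arc weights
*w*, the diversity of a leaf subset X ⊆ Σ is

    rPSD_N(X) = Σ_{e ∈ ↑X} w(e),

the total weight of all arcs having a descendant leaf in X.  On a tree
this is Faith's PD.  The optimization problem — find the size-*m*
subsets maximizing rPSD — is NP-hard on general networks, but exact
greedy algorithms exist on restricted classes, driven by *exchange
properties*: families S_{k,d} of swap pairs (A, B) such that on any
semi-d-ary level-k network (reticulation in-degrees ≤ d, at most k
reticulations per biconnected component) every pair of leaf sets X, X'
with |X'| < |X| admits a swap in S_{k,d} that does not decrease
rPSD(X) + rPSD(X').  The package provides:

* rPSD / PD scoring, exact (rational) arithmetic throughout;
* eNewick (hybrid `#H` tags) and edge-list TSV I/O;
* structural analysis: blob decomposition, level, arity, class flags;
* the swap families S_0, S_{1,d}, S_{k,d}, S_d — enumeration, closed-form
  cardinalities, improving-pair search, exchange-property verification;
* exact optimizers: brute force (any network), greedy for trees, for
  galled trees, and for semibinary level-2 / semi-3-ary level-1 networks;
* a brute-force *gap scan* probing the classes where no greedy
  algorithm is known (semibinary level-3, semi-4-ary level-1), emitting
  counterexample certificates if the greedy recursion ever fails;
* seeded random network generators and two exactly-solved fixtures.

## Worked example

The package ships a four-leaf binary galled tree (`example1_fixture()`,
eNewick `(((x1:2,(x2:0.2)#H1:0.5)p:2,(x3:2,#H1:0.3)q:2)s:1,x4:4)r;`)
with reticulation H above leaf x2.  Running
`python examples/optimal_subsets.py` prints:

```
m=0  value=0  Opt_m = {}
m=1  value=6  Opt_m = {x2}
m=2  value=10  Opt_m = {x2,x4}
m=3  value=13  Opt_m = {x1,x3,x4}
m=4  value=14  Opt_m = {x1,x2,x3,x4}
```

Each line is the *complete* family of maximum-rPSD subsets of that
size with its value: the best pair of leaves is {x2, x4} (rPSD 10),
but the best triple {x1, x3, x4} (rPSD 13) does not contain it —
optima on networks need not nest, which is exactly why single-leaf
greedy fails and the replace-leaf-by-pair move of the galled-tree
algorithm is needed.  `python examples/exchange_pairs.py` shows the
same phenomenon at the exchange level: for X = {x1,x3,x4},
X' = {x2,x4} the summed diversity is 23, every single-leaf move drops
it to 21, and the two-for-one swap ({x1,x3},{x2}) restores 23.

A thin CLI wraps the library for shell use:

```sh
netdiv score -n example1.enewick -X x2,x4        # -> 10
netdiv optimize -n example1.enewick --all-m      # the table above
netdiv classify -n example1.enewick              # level, arity, blobs
netdiv scan --class level3-semibinary --n-leaves 7 --reps 20 --seed 1
```

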