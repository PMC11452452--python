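"""Seeded synthetic network factories and worked-example fixtures.

The random factories are convenience samplers for testing the exchange
and optimization machinery: they draw rooted binary trees by sequential
leaf attachment and then graft reticulation blobs of a requested level
k and arity d onto tree arcs.  They are *not* uniform over their class
and carry no biological-realism claims (no coalescent, no hybridization
rates); every accepted output passes validation and classifies at
level ≤ k and arity ≤ d (asserted, with seeded retries).

Weights are exact rationals.  Weight models:

* ``"unit"``            — every arc weight 1;
* ``"int:lo,hi"``       — integers uniform on [lo, hi];
* ``"real:lo,hi"``      — two-decimal rationals uniform on [lo, hi].

:func:`example1_fixture` is the canonical reconstruction of a small
binary galled tree on four leaves whose 15 nonempty-subset rPSD values
are known exactly; it drives many unit tests.  The split of weight 1
across the three arcs touching its reticulation (0.5 / 0.3 / 0.2) is
not identifiable from those 15 values (the three arcs are ancestral
only to x2, so only their sum is observable) and is fixed for
determinism.

:func:`example2_network` builds, for any k ≥ 2, a binary level-k
network with a single blob chaining k reticulations, on leaves
{x_1..x_k, y}; it is the standard witness that the exchange family for
level-k networks cannot be shrunk: for X = {x_1..x_k}, X' = {y} the
only improving pair in S_{k,2} is the full swap (X, X') itself.
"""

from __future__ import annotations

import random
from fractions import Fraction
from typing import Callable, Iterable

import networkx as nx

from .network import PhyloNetwork, classify

__all__ = [
    "random_tree",
    "random_galled_tree",
    "random_level_k",
    "example1_fixture",
    "example2_network",
    "EXAMPLE1_ENEWICK",
]

#: eNewick form of the Example-1 galled tree
EXAMPLE1_ENEWICK = (
    "(((x1:2,(x2:0.2)#H1:0.5)p:2,(x3:2,#H1:0.3)q:2)s:1,x4:4)r;"
)

WeightSampler = Callable[[random.Random], Fraction]


def _weight_sampler(weights: str | WeightSampler) -> WeightSampler:
    if callable(weights):
        return weights
    if weights == "unit":
        return lambda rng: Fraction(1)
    kind, _, rest = weights.partition(":")
    try:
        lo_s, hi_s = rest.split(",")
        if kind == "int":
            lo, hi = int(lo_s), int(hi_s)
            return lambda rng: Fraction(rng.randint(lo, hi))
        if kind == "real":
            lo_c, hi_c = round(float(lo_s) * 100), round(float(hi_s) * 100)
            return lambda rng: Fraction(rng.randint(lo_c, hi_c), 100)
    except ValueError:
        pass
    raise ValueError(
        f"unknown weight model {weights!r} (use 'unit', 'int:lo,hi' or 'real:lo,hi')"
    )


def _assign_weights(g: nx.DiGraph, rng: random.Random, sampler: WeightSampler):
    for u, v in sorted(g.edges):
        g.edges[u, v]["weight"] = sampler(rng)


def _random_tree_graph(n: int, rng: random.Random) -> nx.DiGraph:
    """Rooted binary tree topology by sequential random leaf attachment."""
    g = nx.DiGraph()
    if n == 1:
        g.add_edge("r", "x1")
        return g
    g.add_edge("r", "x1")
    g.add_edge("r", "x2")
    counter = 0
    for i in range(3, n + 1):
        u, v = rng.choice(sorted(g.edges))
        counter += 1
        mid = f"t{counter}"
        g.remove_edge(u, v)
        g.add_edge(u, mid)
        g.add_edge(mid, v)
        g.add_edge(mid, f"x{i}")
    return g


def random_tree(
    n: int, seed: int = 0, weights: str | WeightSampler = "unit"
) -> PhyloNetwork:
    """Random rooted binary tree on leaves x1..xn, deterministic per seed."""
    if n < 1:
        raise ValueError("need at least one leaf")
    rng = random.Random(seed)
    g = _random_tree_graph(n, rng)
    _assign_weights(g, rng, _weight_sampler(weights))
    return PhyloNetwork(g)


def _insert_blob(
    g: nx.DiGraph,
    rng: random.Random,
    k: int,
    d: int,
    blob_nodes: set[str],
    tag: str,
) -> bool:
    """Graft one blob with k reticulations of in-degree <= d onto a tree arc.

    Mutates ``g``; returns False when no suitable attachment arc or
    stealable leaf remains.  ``blob_nodes`` accumulates nodes already
    inside blobs so later blobs attach elsewhere (blobs stay disjoint).
    """
    candidates = [
        (u, v)
        for (u, v) in sorted(g.edges)
        if u not in blob_nodes
        and v not in blob_nodes
        and g.in_degree(v) <= 1
    ]
    if not candidates:
        return False
    u, v = rng.choice(candidates)

    def steal_leaf(exclude: set[str]) -> str | None:
        pool = sorted(
            x
            for x in g
            if g.out_degree(x) == 0
            and x not in exclude
            and g.in_degree(x) == 1
            and (lambda p: g.in_degree(p) <= 1
                 and g.out_degree(p) >= 2
                 and p not in exclude)(next(iter(g.predecessors(x))))
        )
        if not pool:
            return None
        leaf = rng.choice(pool)
        g.remove_edge(next(iter(g.predecessors(leaf))), leaf)
        return leaf

    s = f"s{tag}"
    h = f"h{tag}_1"
    g.remove_edge(u, v)
    g.add_edge(u, s)
    chain_nodes = []
    for p in range(d):  # d paths s -> c_p -> h; lead ret uses full arity
        c = f"c{tag}_{p}"
        chain_nodes.append(c)
        g.add_edge(s, c)
        g.add_edge(c, h)
    g.add_edge(h, v)
    new_blob = {s, h, *chain_nodes}
    # pendant leaves on the cycle's side nodes give the blob a rich
    # cluster (as in real galled trees); without them the gall is a
    # pendant cherry and exchange behaviour degenerates to tree-like
    for c in chain_nodes:
        if rng.random() < 0.8:
            leaf = steal_leaf(new_blob)
            if leaf is not None:
                g.add_edge(c, leaf)

    for extra in range(2, k + 1):
        tree_pool = sorted(new_blob - {f"h{tag}_{i}" for i in range(1, extra + 1)})
        indeg = rng.randint(2, min(d, len(tree_pool)))
        parents = rng.sample(tree_pool, indeg)
        leaf = steal_leaf(new_blob)
        if leaf is None:
            return False
        h2 = f"h{tag}_{extra}"
        for p in parents:
            g.add_edge(p, h2)
        g.add_edge(h2, leaf)
        new_blob.add(h2)

    blob_nodes |= new_blob
    return True


def random_level_k(
    n: int,
    k: int,
    d: int = 2,
    seed: int = 0,
    n_blobs: int = 1,
    weights: str | WeightSampler = "unit",
    max_retries: int = 50,
) -> PhyloNetwork:
    """Random network of level ≤ k with reticulation in-degrees ≤ d.

    Grafts ``n_blobs`` disjoint blobs, each with exactly k
    reticulations, onto a random binary tree on n leaves; extra
    reticulations inside a blob capture existing leaves as their
    children.  The result is validated and classified; on a failed
    draw the seed is perturbed, up to ``max_retries`` times.
    """
    if k < 0 or d < 2:
        raise ValueError("need k >= 0 and d >= 2")
    if n < k + 1:
        raise ValueError("need n >= k+1 leaves to hang a level-k blob")
    if k == 0:
        return random_tree(n, seed, weights)
    last_err: Exception | None = None
    for attempt in range(max_retries):
        rng = random.Random(seed * 1_000_003 + attempt)
        g = _random_tree_graph(n, rng)
        blob_nodes: set[str] = set()
        ok = all(
            _insert_blob(g, rng, k, d, blob_nodes, tag=str(b))
            for b in range(n_blobs)
        )
        if not ok:
            last_err = RuntimeError("ran out of attachment arcs or stealable leaves")
            continue
        _assign_weights(g, rng, _weight_sampler(weights))
        try:
            net = PhyloNetwork(g)
        except Exception as err:  # regenerate on a bad draw
            last_err = err
            continue
        prof = classify(net)
        if prof.level <= k and (prof.arity <= d):
            return net
        last_err = RuntimeError(f"classified as {prof}")
    raise RuntimeError(
        f"could not generate level-{k} semi-{d}-ary network with n={n}, "
        f"seed={seed} after {max_retries} attempts: {last_err}"
    )


def random_galled_tree(
    n: int,
    seed: int = 0,
    n_blobs: int | None = None,
    weights: str | WeightSampler = "unit",
) -> PhyloNetwork:
    """Random galled tree (semibinary, level 1) with one or more galls."""
    if n_blobs is None:
        n_blobs = random.Random(seed * 7_919 + 1).randint(1, max(1, n // 3))
    return random_level_k(n, k=1, d=2, seed=seed, n_blobs=n_blobs, weights=weights)


# -- worked-example fixtures ------------------------------------------


def example1_fixture() -> PhyloNetwork:
    """The four-leaf binary galled tree with known all-subsets rPSD.

    Arcs: r→s (1), r→x4 (4), s→p (2), s→q (2), p→x1 (2), q→x3 (2),
    p→H (0.5), q→H (0.3), H→x2 (0.2); H is the unique reticulation.
    Level 1, arity 2; total weight 14.  All 15 nonempty-subset rPSD
    values are integers (e.g. rPSD({x2}) = 6, rPSD({x2,x4}) = 10,
    rPSD({x1,x3,x4}) = 13).
    """
    F = Fraction
    return PhyloNetwork.from_arcs(
        [
            ("r", "s", F(1)),
            ("r", "x4", F(4)),
            ("s", "p", F(2)),
            ("s", "q", F(2)),
            ("p", "x1", F(2)),
            ("q", "x3", F(2)),
            ("p", "H", F(1, 2)),
            ("q", "H", F(3, 10)),
            ("H", "x2", F(1, 5)),
        ]
    )


def example2_network(
    k: int, weights: str | WeightSampler = "unit", seed: int = 0
) -> PhyloNetwork:
    """Binary level-k network witnessing tightness of the S_{k,2} family.

    Leaves {x_1..x_k, y}.  A spine r→a_1→…→a_{k−1} feeds tree nodes
    v_1..v_k (v_i→x_i and v_i→H_i); the reticulations chain
    H_1→H_2→…→H_k→y, with H_1's second parent the root.  All k
    reticulations share one blob, so the level is exactly k.  Arc
    weights must be strictly positive for the tightness argument.
    """
    if k < 2:
        raise ValueError("need k >= 2")
    arcs: list[tuple[str, str]] = [("r", "a1"), ("r", "H1")]
    for i in range(1, k - 1):
        arcs.append((f"a{i}", f"a{i+1}"))
    for i in range(1, k):
        arcs.append((f"a{i}", f"v{i}"))
    arcs.append((f"a{k-1}", f"v{k}"))
    for i in range(1, k + 1):
        arcs.append((f"v{i}", f"x{i}"))
        arcs.append((f"v{i}", f"H{i}"))
    for i in range(1, k):
        arcs.append((f"H{i}", f"H{i+1}"))
    arcs.append((f"H{k}", "y"))

    rng = random.Random(seed)
    sampler = _weight_sampler(weights)
    weighted = []
    for u, v in arcs:
        w = sampler(rng)
        if w <= 0:
            raise ValueError("example2_network requires strictly positive weights")
        weighted.append((u, v, w))
    return PhyloNetwork.from_arcs(weighted)
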