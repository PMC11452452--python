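"""Rooted phylogenetic networks and structural queries.

A phylogenetic network on a label set Σ is a rooted directed acyclic
(simple) graph in which every node of in-degree ≥ 2 — a *reticulation*,
modelling a hybridization or recombination event — has out-degree exactly
1, and whose leaves (out-degree-0 nodes) are bijectively labelled by Σ.
Elementary nodes (in-degree ≤ 1, out-degree 1) are explicitly permitted.
Arcs carry nonnegative weights, usually branch lengths.

This module provides the :class:`PhyloNetwork` container (backed by a
``networkx.DiGraph``) together with the structural machinery used by the
diversity and optimization layers: ancestor closures, clusters,
biconnected-component (*blob*) decomposition, level, reticulation arity
and the class predicates (tree / semibinary / galled tree / ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import cached_property
from numbers import Real
from typing import Iterable

import networkx as nx

__all__ = [
    "PhyloNetwork",
    "NetworkValidationError",
    "Blob",
    "NetworkProfile",
    "validate",
    "ancestor_arcs",
    "cluster",
    "blobs",
    "level",
    "reticulation_arity",
    "classify",
]

Arc = tuple[str, str]


class NetworkValidationError(ValueError):
    """Raised when a candidate graph violates the network axioms.

    Carries the full list of violations in :attr:`violations`.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid phylogenetic network: " + "; ".join(violations))


def validate(graph: nx.DiGraph) -> list[str]:
    """Check the phylogenetic-network axioms on a weighted digraph.

    Returns the (possibly empty) list of violated invariants; violations
    are data, not exceptions.  Elementary nodes are *not* violations.
    Arc weights are read from the ``weight`` edge attribute (missing
    weights are treated as a violation).
    """
    violations: list[str] = []
    if graph.number_of_nodes() == 0:
        return ["no root (empty graph)"]
    roots = [v for v in graph if graph.in_degree(v) == 0]
    if not roots:
        violations.append("no root (every node has a parent)")
    elif len(roots) > 1:
        violations.append(
            "multiple roots: " + ", ".join(sorted(map(str, roots)))
        )
    if not nx.is_directed_acyclic_graph(graph):
        violations.append("not acyclic")
    for v in sorted(graph, key=str):
        if graph.in_degree(v) >= 2 and graph.out_degree(v) != 1:
            violations.append(
                f"reticulation {v!r} has out-degree {graph.out_degree(v)} != 1"
            )
    for u, v, data in graph.edges(data=True):
        w = data.get("weight")
        if w is None:
            violations.append(f"arc ({u!r},{v!r}) has no weight")
        elif not isinstance(w, Real) or w < 0:
            violations.append(f"arc ({u!r},{v!r}) has negative or non-numeric weight {w!r}")
    return violations


class PhyloNetwork:
    """A weighted rooted phylogenetic network.

    Nodes are identified by strings; leaves are identified with their
    labels (the node id of a leaf *is* its label, which makes leaf
    labels unique by construction).  The constructor validates the
    graph and raises :class:`NetworkValidationError` listing every
    violated invariant.
    """

    def __init__(self, graph: nx.DiGraph):
        problems = validate(graph)
        if problems:
            raise NetworkValidationError(problems)
        self._g = graph
        self.root: str = next(v for v in graph if graph.in_degree(v) == 0)

    # -- construction -------------------------------------------------

    @classmethod
    def from_arcs(cls, arcs: Iterable[tuple[str, str, Real]]) -> "PhyloNetwork":
        """Build a network from ``(parent, child, weight)`` triples."""
        g = nx.DiGraph()
        for u, v, w in arcs:
            g.add_edge(str(u), str(v), weight=w)
        return cls(g)

    # -- basic accessors ----------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    @cached_property
    def leaves(self) -> frozenset[str]:
        """The label set Σ (leaves are identified with their labels)."""
        return frozenset(v for v in self._g if self._g.out_degree(v) == 0)

    @cached_property
    def sorted_leaves(self) -> tuple[str, ...]:
        return tuple(sorted(self.leaves))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def arcs(self) -> frozenset[Arc]:
        return frozenset(self._g.edges)

    def weight(self, u: str, v: str) -> Real:
        return self._g.edges[u, v]["weight"]

    @cached_property
    def total_weight(self) -> Real:
        return sum(d["weight"] for _, _, d in self._g.edges(data=True))

    def children(self, v: str) -> list[str]:
        return sorted(self._g.successors(v))

    def parents(self, v: str) -> list[str]:
        return sorted(self._g.predecessors(v))

    def is_reticulation(self, v: str) -> bool:
        return self._g.in_degree(v) >= 2

    @cached_property
    def reticulations(self) -> frozenset[str]:
        return frozenset(v for v in self._g if self._g.in_degree(v) >= 2)

    def __contains__(self, v: str) -> bool:
        return v in self._g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PhyloNetwork {len(self.nodes)} nodes, {len(self.arcs)} arcs, "
            f"{len(self.leaves)} leaves, root {self.root!r}>"
        )

    # -- equality up to arc sets (node ids literal) --------------------

    def same_as(self, other: "PhyloNetwork") -> bool:
        """Arc-set and weight identity under literal node ids."""
        if self.arcs != other.arcs:
            return False
        return all(
            Fraction(self.weight(u, v)) == Fraction(other.weight(u, v))
            for (u, v) in self.arcs
        )

    def isomorphic_to(self, other: "PhyloNetwork") -> bool:
        """Leaf-label-preserving, weight-preserving isomorphism test."""
        def nm(a, b):
            # leaves must map to the same label; internal ids are free
            a_leaf = a.get("leaf")
            b_leaf = b.get("leaf")
            return a_leaf == b_leaf

        def em(a, b):
            return Fraction(a["weight"]) == Fraction(b["weight"])

        g1 = self._g.copy()
        g2 = other._g.copy()
        for g, net in ((g1, self), (g2, other)):
            for v in g:
                if g.out_degree(v) == 0:
                    g.nodes[v]["leaf"] = v
        return nx.is_isomorphic(g1, g2, node_match=nm, edge_match=em)


# -- structural queries ------------------------------------------------


def _check_labels(net: PhyloNetwork, X: Iterable[str]) -> frozenset[str]:
    X = frozenset(X)
    unknown = X - net.leaves
    if unknown:
        raise KeyError(f"unknown leaf label(s): {sorted(unknown)}")
    return X


def ancestor_arcs(net: PhyloNetwork, X: Iterable[str]) -> frozenset[Arc]:
    """The arc set ↑X: arcs whose head has a descendant leaf in X.

    Computed by reverse reachability from X on the arc reversal of the
    network.  ``ancestor_arcs(net, Σ)`` is the whole arc set.
    """
    X = _check_labels(net, X)
    if not X:
        return frozenset()
    rev = net.graph.reverse(copy=False)
    marked: set[str] = set()
    for x in X:
        if x not in marked:
            marked.add(x)
            marked.update(nx.descendants(rev, x))
    return frozenset((u, v) for (u, v) in net.graph.edges if v in marked)


def cluster(net: PhyloNetwork, v: str) -> frozenset[str]:
    """The cluster C(v): labels of the descendant leaves of v."""
    if v not in net:
        raise KeyError(f"unknown node {v!r}")
    desc = nx.descendants(net.graph, v) | {v}
    return frozenset(desc & net.leaves)


@dataclass(frozen=True)
class Blob:
    """A biconnected component with more than two nodes.

    ``split_node`` is the unique blob node ancestral to every blob
    node; ``exit_reticulations`` are the blob's reticulations with no
    child inside the blob, ``internal_reticulations`` the rest of the
    reticulations whose incoming arcs lie in the blob.
    """

    nodes: frozenset[str]
    arcs: frozenset[Arc]
    split_node: str
    exit_reticulations: frozenset[str]
    internal_reticulations: frozenset[str]

    @property
    def n_reticulations(self) -> int:
        return len(self.exit_reticulations) + len(self.internal_reticulations)


def _biconnected_arc_components(net: PhyloNetwork) -> list[frozenset[Arc]]:
    """Arc sets of the biconnected components of the underlying undirected graph."""
    und = net.graph.to_undirected(as_view=False)
    comps = []
    for edges in nx.biconnected_component_edges(und):
        arcs = frozenset(
            (u, v) if net.graph.has_edge(u, v) else (v, u) for (u, v) in edges
        )
        comps.append(arcs)
    return comps


def blobs(net: PhyloNetwork) -> list[Blob]:
    """Blob decomposition: biconnected components with > 2 nodes.

    Blobs are returned sorted by their split node.  For each blob the
    split node is found as the unique blob node from which every blob
    node is reachable in the directed network; its uniqueness is a
    theorem and is asserted.
    """
    out: list[Blob] = []
    for arcs in _biconnected_arc_components(net):
        nodes = frozenset(u for a in arcs for u in a)
        if len(nodes) <= 2:
            continue
        split_candidates = [
            v for v in nodes if nodes <= (nx.descendants(net.graph, v) | {v})
        ]
        assert len(split_candidates) == 1, (
            f"blob {sorted(nodes)} has {len(split_candidates)} split-node candidates"
        )
        split = split_candidates[0]
        # reticulations belonging to this blob: incoming arcs inside it
        rets = frozenset(
            v for v in nodes
            if net.is_reticulation(v)
            and all((p, v) in arcs for p in net.graph.predecessors(v))
        )
        exits = frozenset(
            h for h in rets
            if not any((h, c) in arcs for c in net.graph.successors(h))
        )
        out.append(
            Blob(
                nodes=nodes,
                arcs=arcs,
                split_node=split,
                exit_reticulations=exits,
                internal_reticulations=rets - exits,
            )
        )
    out.sort(key=lambda b: b.split_node)
    return out


def level(net: PhyloNetwork) -> int:
    """The level: max number of reticulations in a biconnected component.

    A reticulation is counted in the (unique) component containing its
    incoming arcs.  Trees have level 0.
    """
    bs = blobs(net)
    return max((b.n_reticulations for b in bs), default=0)


def reticulation_arity(net: PhyloNetwork) -> int:
    """Max in-degree over reticulations; 0 for a reticulation-free network."""
    return max((net.graph.in_degree(v) for v in net.reticulations), default=0)


@dataclass(frozen=True)
class NetworkProfile:
    """Structural classification of a network.

    ``arity`` is 0 for trees, so ``is_semi_d_ary(d)`` is vacuously true
    on trees for every d ≥ 2 (the bound quantifies over an empty set of
    reticulations).
    """

    level: int
    arity: int
    is_tree: bool
    is_binary: bool
    is_semibinary: bool
    is_galled_tree: bool

    def is_semi_d_ary(self, d: int) -> bool:
        return self.arity <= d


def classify(net: PhyloNetwork) -> NetworkProfile:
    """Compute level, reticulation arity and the standard class flags."""
    k = level(net)
    d = reticulation_arity(net)
    semibinary = d <= 2
    internal_tree_nodes = [
        v for v in net.graph
        if net.graph.in_degree(v) <= 1 and net.graph.out_degree(v) >= 1
    ]
    binary = semibinary and all(
        net.graph.out_degree(v) == 2 for v in internal_tree_nodes
    )
    return NetworkProfile(
        level=k,
        arity=d,
        is_tree=(k == 0),
        is_binary=binary,
        is_semibinary=semibinary,
        is_galled_tree=(semibinary and k <= 1),
    )
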