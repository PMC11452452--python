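"""Phylogenetic diversity on trees and networks.

On a weighted phylogenetic tree ``T``, Faith's rooted phylogenetic
diversity of a leaf set ``X`` is the total weight of the subtree
spanning the root and ``X``:  ``PD_T(X) = Σ_{e ∈ ↑X} w(e)``.

The *rooted Phylogenetic Subnet Diversity* (rPSD, also called
AllPaths-PD) generalizes this to networks: the total weight of all
arcs having a descendant leaf in ``X``.  On a tree the two coincide.

rPSD is monotone nondecreasing, subadditive and submodular; the
``check_*`` functions here exercise those inequalities exhaustively
(or on a seeded sample) and return every violating witness — a correct
implementation returns none, and an adversarial set function can be
plugged in as a negative control.

:class:`DiversityTable` is the workhorse for enumeration-heavy callers
(optimizers, exchange-property scans): it precomputes rPSD for *all*
2^n leaf subsets, encoded as bitmasks over the sorted label list, with
values scaled to a common integer denominator so that comparisons and
tie detection are exact.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd, isclose
from numbers import Real
from typing import Callable, Iterable

from .network import PhyloNetwork, ancestor_arcs, cluster, level

__all__ = [
    "rpsd",
    "pd_tree",
    "DiversityTable",
    "check_monotone",
    "check_subadditive",
    "check_submodular",
]

#: relative tolerance used to group near-ties when weights are floats
FLOAT_RTOL = 1e-9

_MAX_TABLE_LEAVES = 22


def rpsd(net: PhyloNetwork, X: Iterable[str]) -> Real:
    """rPSD of the leaf set ``X``: total weight of the arcs in ↑X.

    A single reverse reachability pass, O(|E|) per query.
    ``rpsd(net, ∅) = 0`` and ``rpsd(net, Σ)`` is the total weight.
    """
    arcs = ancestor_arcs(net, X)
    return sum((net.weight(u, v) for (u, v) in arcs), Fraction(0))


def pd_tree(tree: PhyloNetwork, X: Iterable[str]) -> Real:
    """Faith's PD on a phylogenetic tree (rPSD with a tree precondition)."""
    if level(tree) != 0:
        raise ValueError("pd_tree requires a phylogenetic tree (level 0)")
    return rpsd(tree, X)


class DiversityTable:
    """All-subsets rPSD table over bitmask-encoded leaf sets.

    Bit ``i`` of a mask corresponds to ``labels[i]`` (labels sorted).
    When every arc weight is rational the raw entries are integers on a
    common denominator :attr:`scale` and all comparisons are exact;
    with float weights ``scale`` is ``None`` and near-ties within
    ``FLOAT_RTOL`` are grouped together.
    """

    def __init__(self, net: PhyloNetwork):
        labels = net.sorted_leaves
        n = len(labels)
        if n > _MAX_TABLE_LEAVES:
            raise ValueError(
                f"refusing to tabulate 2^{n} subsets (> {_MAX_TABLE_LEAVES} leaves)"
            )
        self.net = net
        self.labels: tuple[str, ...] = labels
        self.n = n
        self._bit = {lab: 1 << i for i, lab in enumerate(labels)}

        weights = [net.weight(u, v) for (u, v) in sorted(net.arcs)]
        exact = all(isinstance(w, (int, Fraction)) for w in weights)
        if exact:
            fracs = [Fraction(w) for w in weights]
            scale = 1
            for f in fracs:
                scale = scale * f.denominator // gcd(scale, f.denominator)
            raw_w = [int(f * scale) for f in fracs]
            self.scale: int | None = scale
        else:
            raw_w = [float(w) for w in weights]
            self.scale = None

        # per-arc mask of descendant leaves of the arc's head
        arc_masks = []
        for (u, v) in sorted(net.arcs):
            m = 0
            for lab in cluster(net, v):
                m |= self._bit[lab]
            arc_masks.append(m)

        size = 1 << n
        raws = [0] * size if self.scale is not None else [0.0] * size
        for m, w in zip(arc_masks, raw_w):
            for X in range(1, size):
                if X & m:
                    raws[X] += w
        self._raws = raws
        self.total_raw = raws[size - 1] if n else (0 if self.scale else 0.0)

    # -- encoding ------------------------------------------------------

    def mask_of(self, X: Iterable[str]) -> int:
        m = 0
        for lab in X:
            try:
                m |= self._bit[lab]
            except KeyError:
                raise KeyError(f"unknown leaf label {lab!r}") from None
        return m

    def set_of(self, mask: int) -> frozenset[str]:
        return frozenset(
            lab for lab, b in self._bit.items() if mask & b
        )

    # -- values --------------------------------------------------------

    def raw(self, mask: int) -> Real:
        """Scaled rPSD of the subset encoded by ``mask``."""
        return self._raws[mask]

    def value(self, X: Iterable[str]) -> Real:
        """rPSD of a leaf set, in the original weight units."""
        r = self._raws[self.mask_of(X)]
        return Fraction(r, self.scale) if self.scale is not None else r

    def unscale(self, raw: Real) -> Real:
        return Fraction(raw, self.scale) if self.scale is not None else raw

    def raw_eq(self, a: Real, b: Real) -> bool:
        """Exact equality for rational tables; FLOAT_RTOL grouping otherwise."""
        if self.scale is not None:
            return a == b
        return isclose(a, b, rel_tol=FLOAT_RTOL, abs_tol=0.0)


# -- property checks ---------------------------------------------------


def _all_values(
    net: PhyloNetwork | None,
    fn: Callable[[frozenset[str]], Real] | None,
    labels: Iterable[str] | None,
) -> tuple[tuple[str, ...], list[Real], Callable[[Real, Real], bool]]:
    """Tabulate the set function over all subsets (masks) of the universe."""
    if fn is None:
        if net is None:
            raise ValueError("provide a network or an explicit set function")
        tab = DiversityTable(net)
        eq = tab.raw_eq
        return tab.labels, tab._raws, eq
    labs = tuple(sorted(labels if labels is not None else net.sorted_leaves))
    if len(labs) > 16:
        raise ValueError("exhaustive check limited to 16 labels for a plain fn")
    vals = []
    for m in range(1 << len(labs)):
        vals.append(fn(frozenset(l for i, l in enumerate(labs) if m & (1 << i))))
    return labs, vals, (lambda a, b: a == b)


def _decode(labs: tuple[str, ...], m: int) -> frozenset[str]:
    return frozenset(l for i, l in enumerate(labs) if m & (1 << i))


def check_monotone(net=None, *, fn=None, labels=None) -> list[tuple]:
    """Witnesses (X, Y) with X ⊆ Y but value(X) > value(Y); [] if monotone."""
    labs, vals, _ = _all_values(net, fn, labels)
    out = []
    full = (1 << len(labs)) - 1
    for Y in range(full + 1):
        vY = vals[Y]
        # drop one element at a time; pairwise monotonicity implies the rest
        b = Y
        while b:
            low = b & -b
            if vals[Y ^ low] > vY:
                out.append((_decode(labs, Y ^ low), _decode(labs, Y)))
            b ^= low
    return out


def check_subadditive(net=None, *, fn=None, labels=None) -> list[tuple]:
    """Witnesses (X, Y) with value(X ∪ Y) > value(X) + value(Y)."""
    labs, vals, _ = _all_values(net, fn, labels)
    out = []
    full = (1 << len(labs)) - 1
    for X in range(full + 1):
        for Y in range(X, full + 1):
            if vals[X | Y] > vals[X] + vals[Y]:
                out.append((_decode(labs, X), _decode(labs, Y)))
    return out


def check_submodular(net=None, *, fn=None, labels=None) -> list[tuple]:
    """Witnesses (X, Y, a) with X ⊆ Y, a ∉ Y violating the diminishing-returns
    inequality value(Y∪{a}) − value(Y) ≤ value(X∪{a}) − value(X)."""
    labs, vals, _ = _all_values(net, fn, labels)
    n = len(labs)
    out = []
    full = (1 << n) - 1
    for Y in range(full + 1):
        # iterate X over all submasks of Y
        X = Y
        while True:
            rest = full & ~Y
            b = rest
            while b:
                low = b & -b
                if vals[Y | low] - vals[Y] > vals[X | low] - vals[X]:
                    out.append(
                        (_decode(labs, X), _decode(labs, Y), _decode(labs, low))
                    )
                b ^= low
            if X == 0:
                break
            X = (X - 1) & Y
    return out
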