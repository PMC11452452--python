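"""Exchange pairs and the generalized exchange property.

Faith's PD on trees satisfies Steel's *strong exchange property*: for
any two leaf sets X, X' with |X'| < |X| some single leaf can be moved
from X to X' without decreasing the summed diversity.  On networks
rPSD loses this property, but it regains an exchange property with
respect to richer families of *swap pairs* (A, B) — remove A from X
and hand it to X', take B back — whose shape depends only on the
network's level k and reticulation arity d:

* ``S0``            = { ({x}, ∅) }                          (trees)
* ``S_{1,d}``       = S0 ∪ { (A,B) : 1 ≤ |B| < |A| ≤ d }
* ``S_{k,d}, k≥2``  = S0 ∪ { (A,B) : 1 ≤ |B| < |A| < dk, |A|−|B| ≤ (d−1)k }
* ``S_d``           = S0 ∪ { (A,{b}) : b ∉ A, 1 < |A| ≤ d }  (level-1 refinement)

A pair (A, B) with A ⊆ X∖X', B ⊆ X'∖X, |B| < |A| is *improving* for
(X, X') when rPSD(X) + rPSD(X') ≤ rPSD(τ_{A,B}(X)) + rPSD(τ_{B,A}(X')),
where τ_{S,T}(X) = (X∖S) ∪ T.  The inequality is deliberately
non-strict, so the full swap (X∖X', X'∖X) — when admissible — is
always improving; family restriction is what gives the property bite.

On a semi-d-ary level-k network every (X, X') admits an improving pair
in S_{k,d}; on semi-d-ary level-1 networks already in S_d, and any
improving pair (A, {b}) with |A| ≥ 2 is localized by a blob: there is
a blob with exit reticulation H and split node v such that
X ∩ C(H) = ∅, b ∈ C(H) and A ⊆ C(v).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Iterable, Iterator, Literal

import random

from .network import Blob, PhyloNetwork, blobs, cluster, level
from .diversity import DiversityTable, rpsd

__all__ = [
    "SwapPair",
    "SwapFamily",
    "swap",
    "family_size",
    "is_improving",
    "find_improving_pair",
    "verify_exchange_property",
    "Corollary1Witness",
    "corollary1_witness",
]


@dataclass(frozen=True)
class SwapPair:
    """An exchange candidate (A, B): disjoint leaf sets with |B| < |A|."""

    A: frozenset[str]
    B: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "A", frozenset(self.A))
        object.__setattr__(self, "B", frozenset(self.B))
        if self.A & self.B:
            raise ValueError("A and B must be disjoint")
        if len(self.B) >= len(self.A):
            raise ValueError("|B| must be smaller than |A|")

    @property
    def j(self) -> int:
        """The cardinality jump |A| − |B| ≥ 1."""
        return len(self.A) - len(self.B)

    def __repr__(self) -> str:
        return (
            "({" + ",".join(sorted(self.A)) + "},{"
            + ",".join(sorted(self.B)) + "})"
        )


def swap(X: Iterable[str], S: Iterable[str], T: Iterable[str]) -> frozenset[str]:
    """τ_{S,T}(X) = (X∖S) ∪ T.  Requires S ⊆ X and T ∩ X = ∅."""
    X, S, T = frozenset(X), frozenset(S), frozenset(T)
    if not S <= X:
        raise ValueError("S must be a subset of X")
    if T & X:
        raise ValueError("T must be disjoint from X")
    return (X - S) | T


class SwapFamily:
    """An enumerable family of swap pairs over a label universe.

    Construct via :meth:`s0`, :meth:`skd` or :meth:`sd`.  Iteration is
    deterministic: increasing |A|, then |B|, then lexicographic on the
    sorted labels of A then B.  ``Skd`` with k = 0 degenerates to S0
    (the tree case), and ``Skd(2,2)`` equals ``Skd(1,3)`` as a set.
    """

    def __init__(self, kind: Literal["S0", "Skd", "Sd"], labels: Iterable[str],
                 k: int | None = None, d: int | None = None):
        self.kind = kind
        self.labels: tuple[str, ...] = tuple(sorted(set(labels)))
        self.k = k
        self.d = d
        if kind == "Skd":
            if k is None or d is None or k < 0 or d < 2:
                raise ValueError("Skd requires k >= 0 and d >= 2")
        elif kind == "Sd":
            if d is None or d < 2:
                raise ValueError("Sd requires d >= 2")
        elif kind != "S0":
            raise ValueError(f"unknown family kind {kind!r}")

    # -- constructors --------------------------------------------------

    @classmethod
    def s0(cls, labels: Iterable[str]) -> "SwapFamily":
        return cls("S0", labels)

    @classmethod
    def skd(cls, k: int, d: int, labels: Iterable[str]) -> "SwapFamily":
        return cls("Skd", labels, k=k, d=d)

    @classmethod
    def sd(cls, d: int, labels: Iterable[str]) -> "SwapFamily":
        return cls("Sd", labels, d=d)

    @classmethod
    def for_network(cls, net: PhyloNetwork) -> "SwapFamily":
        """The family S_{k,d} matching the network's level and arity."""
        from .network import classify

        prof = classify(net)
        if prof.is_tree:
            return cls.s0(net.leaves)
        return cls.skd(prof.level, max(prof.arity, 2), net.leaves)

    # -- admissible size pairs ----------------------------------------

    def size_pairs(self) -> list[tuple[int, int]]:
        """Admissible (|A|, |B|) combinations, sorted by (|A|, |B|)."""
        out = [(1, 0)]
        if self.kind == "S0" or (self.kind == "Skd" and self.k == 0):
            return out
        if self.kind == "Sd":
            out += [(a, 1) for a in range(2, self.d + 1)]
            return out
        k, d = self.k, self.d
        if k == 1:
            for a in range(2, d + 1):
                for b in range(1, a):
                    out.append((a, b))
        else:
            for a in range(2, d * k):
                for b in range(max(1, a - (d - 1) * k), a):
                    out.append((a, b))
        return sorted(out)

    # -- membership and enumeration -----------------------------------

    def __contains__(self, pair: SwapPair) -> bool:
        if not (pair.A | pair.B) <= set(self.labels):
            return False
        return (len(pair.A), len(pair.B)) in set(self.size_pairs())

    def iter_restricted(
        self, A_pool: Iterable[str], B_pool: Iterable[str]
    ) -> Iterator[SwapPair]:
        """Members with A ⊆ A_pool and B ⊆ B_pool, in canonical order."""
        A_pool = sorted(set(A_pool))
        B_pool = sorted(set(B_pool))
        for a, b in self.size_pairs():
            if a > len(A_pool) or b > len(B_pool):
                continue
            for A in combinations(A_pool, a):
                A_set = frozenset(A)
                for B in combinations(sorted(set(B_pool) - A_set), b):
                    yield SwapPair(A_set, frozenset(B))

    def __iter__(self) -> Iterator[SwapPair]:
        yield from self.iter_restricted(self.labels, self.labels)

    def __len__(self) -> int:
        return family_size(self.kind, len(self.labels), k=self.k, d=self.d)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind == "Skd":
            return f"S_{{{self.k},{self.d}}} on {len(self.labels)} labels"
        if self.kind == "Sd":
            return f"S_{self.d} on {len(self.labels)} labels"
        return f"S_0 on {len(self.labels)} labels"


def family_size(kind: str, n: int, k: int | None = None, d: int | None = None) -> int:
    """Closed-form family cardinalities.

    |S_0| = n;
    |S_{1,d}| = n + Σ_{j=2}^{d} Σ_{i=1}^{j−1} C(n,j)·C(n−j,i);
    |S_{k,d}| = n + Σ_{j=2}^{dk−1} Σ_{i=j−(d−1)k}^{j−1} C(n,j)·C(n−j,i)  (k ≥ 2),
    with the inner index clamped to i ≥ 1 (the set definition requires
    a nonempty B outside S_0);
    |S_d| = n + Σ_{a=2}^{d} C(n,a)·(n−a).
    """
    if kind == "S0" or (kind == "Skd" and k == 0):
        return n
    if kind == "Sd":
        return n + sum(comb(n, a) * (n - a) for a in range(2, d + 1))
    if kind != "Skd":
        raise ValueError(f"unknown family kind {kind!r}")
    if k == 1:
        return n + sum(
            comb(n, j) * comb(n - j, i)
            for j in range(2, min(d, n) + 1)
            for i in range(1, j)
        )
    return n + sum(
        comb(n, j) * comb(n - j, i)
        for j in range(2, min(d * k - 1, n) + 1)
        for i in range(max(1, j - (d - 1) * k), j)
    )


# -- improving pairs ---------------------------------------------------


def _value_fn(net: PhyloNetwork, table: DiversityTable | None) -> Callable:
    if table is not None:
        return lambda X: table.raw(table.mask_of(X))
    cache: dict[frozenset[str], object] = {}

    def val(X: frozenset[str]):
        if X not in cache:
            cache[X] = rpsd(net, X)
        return cache[X]

    return val


def is_improving(
    net: PhyloNetwork,
    X: Iterable[str],
    X_prime: Iterable[str],
    pair: SwapPair,
    table: DiversityTable | None = None,
) -> bool:
    """Non-strict improving-pair test for (X, X') with |X'| < |X|.

    True iff rPSD(X) + rPSD(X') ≤ rPSD(τ_{A,B}(X)) + rPSD(τ_{B,A}(X')).
    """
    X = frozenset(X)
    Xp = frozenset(X_prime)
    if len(Xp) >= len(X):
        raise ValueError("requires |X'| < |X|")
    if not pair.A <= X - Xp:
        raise ValueError("pair.A must be a subset of X \\ X'")
    if not pair.B <= Xp - X:
        raise ValueError("pair.B must be a subset of X' \\ X")
    val = _value_fn(net, table)
    lhs = val(X) + val(Xp)
    rhs = val(swap(X, pair.A, pair.B)) + val(swap(Xp, pair.B, pair.A))
    return lhs <= rhs


def find_improving_pair(
    net: PhyloNetwork,
    X: Iterable[str],
    X_prime: Iterable[str],
    fam: SwapFamily,
    mode: Literal["first", "all"] = "first",
    table: DiversityTable | None = None,
):
    """Scan ``fam`` (restricted to A ⊆ X∖X', B ⊆ X'∖X) for improving pairs.

    Returns the first improving pair in canonical order (or None), or
    the full list when ``mode="all"``.  On a semi-d-ary level-k network
    with ``fam = S_{k,d}`` the exchange property guarantees a non-None
    result — callers should assert, not assume.
    """
    X = frozenset(X)
    Xp = frozenset(X_prime)
    if len(Xp) >= len(X):
        raise ValueError("requires |X'| < |X|")
    val = _value_fn(net, table)
    lhs = val(X) + val(Xp)
    found = []
    for pair in fam.iter_restricted(X - Xp, Xp - X):
        rhs = val((X - pair.A) | pair.B) + val((Xp - pair.B) | pair.A)
        if lhs <= rhs:
            if mode == "first":
                return pair
            found.append(pair)
    return None if mode == "first" else found


def verify_exchange_property(
    net: PhyloNetwork,
    fam: SwapFamily,
    scope: Literal["exhaustive", "sample"] = "exhaustive",
    n_pairs: int = 1000,
    seed: int = 0,
    table: DiversityTable | None = None,
):
    """Search for a pair (X, X') with *no* improving pair in ``fam``.

    Returns the first counterexample (X, X') found, else None.
    Exhaustive scope iterates every X, X' ⊆ Σ with |X'| < |X| and is
    guarded to ≤ 8 leaves; sample scope draws ``n_pairs`` seeded pairs.
    """
    labels = net.sorted_leaves
    n = len(labels)
    if table is None:
        table = DiversityTable(net)

    def no_improving(X: frozenset[str], Xp: frozenset[str]) -> bool:
        return find_improving_pair(net, X, Xp, fam, table=table) is None

    if scope == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive scope limited to 8 leaves")
        masks_by_size: dict[int, list[int]] = {}
        for m in range(1 << n):
            masks_by_size.setdefault(bin(m).count("1"), []).append(m)
        for sz_x in range(1, n + 1):
            for sz_xp in range(sz_x):
                for mx in masks_by_size[sz_x]:
                    X = table.set_of(mx)
                    for mxp in masks_by_size[sz_xp]:
                        Xp = table.set_of(mxp)
                        if no_improving(X, Xp):
                            return (X, Xp)
        return None

    rng = random.Random(seed)
    for _ in range(n_pairs):
        sz_x = rng.randint(1, n)
        sz_xp = rng.randint(0, sz_x - 1)
        X = frozenset(rng.sample(labels, sz_x))
        Xp = frozenset(rng.sample(labels, sz_xp))
        if no_improving(X, Xp):
            return (X, Xp)
    return None


# -- Corollary-1 localization -----------------------------------------


@dataclass(frozen=True)
class Corollary1Witness:
    """A blob certifying an improving pair (A, {b}) on a level-1 network."""

    blob: Blob
    exit_reticulation: str
    split_node: str


def corollary1_witness(
    net: PhyloNetwork,
    X: Iterable[str],
    X_prime: Iterable[str],
    pair: SwapPair,
) -> Corollary1Witness | None:
    """Locate a blob witnessing an improving pair (A, {b}), |A| ≥ 2.

    On a semi-d-ary level-1 network, any such improving pair admits a
    blob with exit reticulation H and split node v with X ∩ C(H) = ∅,
    b ∈ C(H) and A ⊆ C(v).  Returns None when no blob qualifies
    (trees, having no blobs, always return None).
    """
    if level(net) > 1:
        raise ValueError("corollary1_witness requires a level-<=1 network")
    if len(pair.B) != 1 or len(pair.A) < 2:
        raise ValueError("pair must have |B| = 1 and |A| >= 2")
    X = frozenset(X)
    (b,) = pair.B
    for blob in blobs(net):
        C_v = cluster(net, blob.split_node)
        if not pair.A <= C_v:
            continue
        for H in sorted(blob.exit_reticulations):
            C_H = cluster(net, H)
            if b in C_H and not (X & C_H):
                return Corollary1Witness(blob, H, blob.split_node)
    return None
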