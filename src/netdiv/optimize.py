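"""rPSD-optimal leaf subsets: brute force, greedy algorithms, gap scans.

``Opt_m`` denotes the family of *all* size-m leaf subsets of maximum
rPSD.  Finding it is NP-hard on general networks, but exchange
properties yield exact greedy algorithms on restricted classes:

* phylogenetic trees — grow every optimum by one best leaf at a time
  (Steel's strong exchange property);
* galled trees — ``Opt_m = Opt-τ_{1,2,1}(Opt_{m−1})``: every optimum
  arises from an optimum one size down by optimally adding a leaf or
  optimally replacing a leaf by a pair;
* semibinary level-2 and semi-3-ary level-1 networks —
  ``Opt_m ⊆ Opt-τ_{2,2,1}(Opt_{m−1}) ∪ Opt-τ_{2,2,2}(Opt_{m−2})``:
  additionally replace a pair by a triple (from Opt_{m−1}) or a leaf
  by a triple (from Opt_{m−2}); on semi-3-ary level-1 networks the
  pair-by-triple move is never needed.

For one complexity level further (semibinary level-3, semi-4-ary
level-1) no greedy algorithm is known; :func:`gap_scan` tests, fully
by brute force, whether ``Opt_m ⊆ ∪_{j≤J} Opt-τ_{k,d,j}(Opt_{m−j})``
holds on a given network and emits counterexample certificates when it
does not.  A certified violation would settle an open question, so the
scan treats it as a reportable artifact rather than an error.

All optima are defined by exact maxima; with rational weights the
comparisons are exact integer comparisons (see
:class:`~netdiv.diversity.DiversityTable`), and with float weights
near-ties within 1e-9 relative tolerance are grouped into the optimal
family (documented as approximate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from numbers import Real
from typing import Iterable, Iterator, Literal

from .diversity import DiversityTable
from .exchange import SwapFamily, SwapPair
from .network import PhyloNetwork, classify

__all__ = [
    "OptFamily",
    "OptSequence",
    "GapScanReport",
    "brute_force_opt",
    "opt_tau_expand",
    "opt_tau_contract",
    "greedy_tree",
    "greedy_galled",
    "greedy_level2",
    "dispatch_optimize",
    "gap_scan",
    "chain_step",
]

#: brute-force enumeration guard
MAX_BRUTE_LEAVES = 20
#: default cap on the number of tied sets retained per cardinality
MAX_FAMILY = 10_000


@dataclass(frozen=True)
class OptFamily:
    """All maximum-rPSD leaf subsets of one cardinality, with their value."""

    m: int
    value: Real
    sets: frozenset[frozenset[str]]

    def representative(self) -> frozenset[str]:
        """Deterministic member: lexicographically least sorted tuple."""
        return min(self.sets, key=lambda s: tuple(sorted(s)))


@dataclass(frozen=True)
class OptSequence:
    """Optimal families for every cardinality m = 0..n."""

    families: tuple[OptFamily, ...]

    def __getitem__(self, m: int) -> OptFamily:
        return self.families[m]

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[OptFamily]:
        return iter(self.families)

    @property
    def values(self) -> tuple[Real, ...]:
        return tuple(f.value for f in self.families)


class FamilySizeError(RuntimeError):
    """Raised when a tied optimal family exceeds the configured cap."""


# -- mask-level helpers ------------------------------------------------


def _argmax(table: DiversityTable, masks: Iterable[int], max_family: int):
    """(best raw value, all masks attaining it) with float-tie grouping."""
    best = None
    best_masks: set[int] = set()
    for m in masks:
        r = table.raw(m)
        if best is None or (r > best and not table.raw_eq(r, best)):
            best = r
            best_masks = {m}
        elif table.raw_eq(r, best):
            best_masks.add(m)
            if len(best_masks) > max_family:
                raise FamilySizeError(
                    f"more than {max_family} tied optimal sets; "
                    "raise max_family to proceed"
                )
    return best, best_masks


def _family(table: DiversityTable, m: int, raw, masks: set[int]) -> OptFamily:
    return OptFamily(
        m=m,
        value=table.unscale(raw),
        sets=frozenset(table.set_of(x) for x in masks),
    )


def _expand_masks(table: DiversityTable, Y: int, j: int, fam: SwapFamily) -> set[int]:
    """Masks τ_{B,A}(Y) with (A,B) ∈ fam, B ⊆ Y, A ⊆ Σ∖Y, |A|−|B| = j."""
    n = table.n
    y_bits = [i for i in range(n) if Y >> i & 1]
    out_bits = [i for i in range(n) if not Y >> i & 1]
    cands: set[int] = set()
    for a, b in fam.size_pairs():
        if a - b != j or b > len(y_bits) or a > len(out_bits):
            continue
        for B in combinations(y_bits, b):
            base = Y
            for i in B:
                base &= ~(1 << i)
            for A in combinations(out_bits, a):
                m = base
                for i in A:
                    m |= 1 << i
                cands.add(m)
    return cands


def _contract_masks(table: DiversityTable, Y: int, j: int, fam: SwapFamily) -> set[int]:
    """Masks τ_{A,B}(Y) with (A,B) ∈ fam, A ⊆ Y, B ⊆ Σ∖Y, |A|−|B| = j."""
    n = table.n
    y_bits = [i for i in range(n) if Y >> i & 1]
    out_bits = [i for i in range(n) if not Y >> i & 1]
    cands: set[int] = set()
    for a, b in fam.size_pairs():
        if a - b != j or a > len(y_bits) or b > len(out_bits):
            continue
        for A in combinations(y_bits, a):
            base = Y
            for i in A:
                base &= ~(1 << i)
            for B in combinations(out_bits, b):
                m = base
                for i in B:
                    m |= 1 << i
                cands.add(m)
    return cands


# -- exact brute force -------------------------------------------------


def brute_force_opt(
    net: PhyloNetwork,
    m: int,
    table: DiversityTable | None = None,
    max_family: int = MAX_FAMILY,
) -> OptFamily:
    """Exact maximum and *all* argmax sets of cardinality m, by enumeration."""
    n = len(net.leaves)
    if not 0 <= m <= n:
        raise ValueError(f"m must be between 0 and {n}")
    if n > MAX_BRUTE_LEAVES:
        raise ValueError(f"brute force guarded to {MAX_BRUTE_LEAVES} leaves")
    if table is None:
        table = DiversityTable(net)
    masks = (
        sum(1 << i for i in bits) for bits in combinations(range(n), m)
    )
    raw, best = _argmax(table, masks, max_family)
    return _family(table, m, raw, best)


def _brute_sequence(net, table, max_family) -> OptSequence:
    fams = tuple(
        brute_force_opt(net, m, table=table, max_family=max_family)
        for m in range(len(net.leaves) + 1)
    )
    return OptSequence(fams)


# -- Opt-τ expansion / contraction ------------------------------------


def opt_tau_expand(
    net: PhyloNetwork,
    X: Iterable[str],
    j: int,
    fam: SwapFamily,
    table: DiversityTable | None = None,
    max_family: int = MAX_FAMILY,
) -> OptFamily:
    """Opt-τ_{k,d,j}(X): the max-rPSD sets of size |X|+j reachable from X
    by one admissible swap τ_{B,A} with (A,B) ∈ fam and |A|−|B| = j."""
    if table is None:
        table = DiversityTable(net)
    Y = table.mask_of(X)
    cands = _expand_masks(table, Y, j, fam)
    if not cands:
        raise ValueError(f"no expansion candidate for |X|={bin(Y).count('1')}, j={j}")
    raw, best = _argmax(table, cands, max_family)
    return _family(table, bin(Y).count("1") + j, raw, best)


def opt_tau_contract(
    net: PhyloNetwork,
    X: Iterable[str],
    j: int,
    fam: SwapFamily,
    table: DiversityTable | None = None,
    max_family: int = MAX_FAMILY,
) -> OptFamily:
    """Opt-τ⁻¹_{k,d,j}(X): max-rPSD sets of size |X|−j one swap below X."""
    if table is None:
        table = DiversityTable(net)
    Y = table.mask_of(X)
    cands = _contract_masks(table, Y, j, fam)
    if not cands:
        raise ValueError(f"no contraction candidate for |X|={bin(Y).count('1')}, j={j}")
    raw, best = _argmax(table, cands, max_family)
    return _family(table, bin(Y).count("1") - j, raw, best)


# -- greedy algorithms -------------------------------------------------


def _greedy_by_pools(
    net: PhyloNetwork,
    size_pairs_prev: list[tuple[int, int]],
    size_pairs_prev2: list[tuple[int, int]],
    table: DiversityTable | None,
    max_family: int,
) -> OptSequence:
    """Shared engine: Opt_m = argmax over swap candidates pooled from the
    previous one or two optimal families.

    The pooled candidate family contains the relevant Opt-τ unions and
    consists of size-m sets only, so its argmax is exactly Opt_m
    whenever the class's containment result holds.
    """
    if table is None:
        table = DiversityTable(net)
    n = table.n

    class _Pairs:
        def __init__(self, pairs):
            self._pairs = pairs

        def size_pairs(self):
            return self._pairs

    fam1 = _Pairs(size_pairs_prev)
    fam2 = _Pairs(size_pairs_prev2)

    fams: list[OptFamily] = [OptFamily(0, table.unscale(table.raw(0)), frozenset([frozenset()]))]
    prev_masks: set[int] = {0}
    prev2_masks: set[int] = set()
    for m in range(1, n + 1):
        pool: set[int] = set()
        for Y in prev_masks:
            pool |= _expand_masks(table, Y, 1, fam1)
        if size_pairs_prev2:
            for Y in prev2_masks:
                pool |= _expand_masks(table, Y, 2, fam2)
        raw, best = _argmax(table, pool, max_family)
        fams.append(_family(table, m, raw, best))
        prev2_masks = prev_masks
        prev_masks = best
    return OptSequence(tuple(fams))


def greedy_tree(
    tree: PhyloNetwork,
    table: DiversityTable | None = None,
    max_family: int = MAX_FAMILY,
) -> OptSequence:
    """Greedy for phylogenetic trees: grow each optimum by one best leaf.

    Exact on trees for every m (all tied optima are propagated).
    """
    if classify(tree).level != 0:
        raise ValueError("greedy_tree requires a phylogenetic tree")
    return _greedy_by_pools(tree, [(1, 0)], [], table, max_family)


def greedy_galled(
    net: PhyloNetwork,
    mode: Literal["full", "representative"] = "full",
    table: DiversityTable | None = None,
    max_family: int = MAX_FAMILY,
) -> OptSequence:
    """Greedy for galled trees via Opt_m = Opt-τ_{1,2,1}(Opt_{m−1}).

    ``full`` propagates entire families and is exact.
    ``representative`` keeps one set per cardinality: from a single
    Y_{m−1} the per-set optimum Opt-τ_{1,2,1}(Y_{m−1}) is still
    contained in Opt_m, so every returned representative is a true
    optimum (this shortcut is only proven for galled trees).
    """
    prof = classify(net)
    if not prof.is_galled_tree:
        raise ValueError("greedy_galled requires a galled tree (semibinary, level <= 1)")
    if table is None:
        table = DiversityTable(net)
    if mode == "full":
        return _greedy_by_pools(net, [(1, 0), (2, 1)], [], table, max_family)
    fam = SwapFamily.skd(1, 2, net.leaves)
    fams: list[OptFamily] = [OptFamily(0, table.unscale(table.raw(0)), frozenset([frozenset()]))]
    Y = frozenset()
    for m in range(1, table.n + 1):
        opt = opt_tau_expand(net, Y, 1, fam, table=table, max_family=max_family)
        Y = opt.representative()
        fams.append(OptFamily(m, opt.value, frozenset([Y])))
    return OptSequence(tuple(fams))


def greedy_level2(
    net: PhyloNetwork,
    table: DiversityTable | None = None,
    max_family: int = MAX_FAMILY,
) -> OptSequence:
    """Greedy for semibinary level-2 or semi-3-ary level-1 networks.

    Candidates for Opt_m pool, from every member of Opt_{m−1}: add one
    leaf, replace a leaf by a pair, replace a pair by a triple (the
    latter skipped on semi-3-ary level-1 networks, where the level-1
    localization shows it is never needed); and from every member of
    Opt_{m−2}: replace a leaf by a triple.  Opt_m is the argmax over
    the pooled candidates; full families are retained throughout.
    """
    prof = classify(net)
    level2_ok = prof.is_semibinary and prof.level <= 2
    semi3_ok = prof.arity <= 3 and prof.level <= 1
    if not (level2_ok or semi3_ok):
        raise ValueError(
            "greedy_level2 requires a semibinary level-<=2 or semi-3-ary "
            "level-<=1 network"
        )
    skip_pair_by_triple = semi3_ok
    j1 = [(1, 0), (2, 1)] + ([] if skip_pair_by_triple else [(3, 2)])
    j2 = [(3, 1)]
    return _greedy_by_pools(net, j1, j2, table, max_family)


def dispatch_optimize(
    net: PhyloNetwork,
    m: int | None = None,
    method: Literal["auto", "brute", "greedy"] = "auto",
    table: DiversityTable | None = None,
    max_family: int = MAX_FAMILY,
):
    """Route to the fastest exact algorithm for the network's class.

    ``auto``: trees → leaf-at-a-time greedy; galled trees → the
    level-1 greedy; semibinary level-2 / semi-3-ary level-1 → the
    level-2 greedy; anything else falls back to brute force with a
    warning (the general problem is NP-hard).  Returns the OptSequence,
    or the single OptFamily when ``m`` is given.
    """
    prof = classify(net)
    if table is None:
        table = DiversityTable(net)

    def greedy_route():
        if prof.is_tree:
            return greedy_tree(net, table=table, max_family=max_family)
        if prof.is_galled_tree:
            return greedy_galled(net, table=table, max_family=max_family)
        if (prof.is_semibinary and prof.level <= 2) or (
            prof.arity <= 3 and prof.level <= 1
        ):
            return greedy_level2(net, table=table, max_family=max_family)
        return None

    if method == "greedy":
        seq = greedy_route()
        if seq is None:
            raise ValueError("no exact greedy algorithm is known for this class")
    elif method == "brute":
        if m is not None:
            return brute_force_opt(net, m, table=table, max_family=max_family)
        seq = _brute_sequence(net, table, max_family)
    else:
        seq = greedy_route()
        if seq is None:
            warnings.warn(
                "rPSD optimization is NP-hard in general and no exact greedy "
                "algorithm is known for this network class; using brute force",
                stacklevel=2,
            )
            if m is not None:
                return brute_force_opt(net, m, table=table, max_family=max_family)
            seq = _brute_sequence(net, table, max_family)
    return seq[m] if m is not None else seq


# -- gap scan ----------------------------------------------------------


@dataclass(frozen=True)
class GapScanReport:
    """Outcome of testing Opt_m ⊆ ∪_{j=1..J} Opt-τ_{k,d,j}(Opt_{m−j}).

    ``satisfied[m]`` is the per-cardinality verdict; every violating
    optimal set is listed in ``counterexamples`` as (m, witness).
    Everything is computed by brute force — never by the greedy under
    test.
    """

    J: int
    family: str
    satisfied: dict[int, bool]
    counterexamples: tuple[tuple[int, frozenset[str]], ...]
    optima: OptSequence

    @property
    def ok(self) -> bool:
        return not self.counterexamples


def gap_scan(
    net: PhyloNetwork,
    J: int = 3,
    fam: SwapFamily | None = None,
    table: DiversityTable | None = None,
    max_family: int = MAX_FAMILY,
) -> GapScanReport:
    """Brute-force test of the greedy-reachability containment.

    For each m computes Opt_m by enumeration and checks that every
    member lies in some Opt-τ_{k,d,j}(Opt_{m−j}), j = 1..J, where each
    Opt-τ of a family is the union over its members of their per-set
    expansion optima.
    """
    if table is None:
        table = DiversityTable(net)
    if fam is None:
        fam = SwapFamily.for_network(net)
    n = table.n
    opt = _brute_sequence(net, table, max_family)
    satisfied: dict[int, bool] = {}
    bad: list[tuple[int, frozenset[str]]] = []
    # cache mask-level optimal families
    opt_masks = [
        {table.mask_of(s) for s in opt[m].sets} for m in range(n + 1)
    ]
    for m in range(1, n + 1):
        allowed: set[int] = set()
        for j in range(1, min(J, m) + 1):
            for Y in opt_masks[m - j]:
                cands = _expand_masks(table, Y, j, fam)
                if not cands:
                    continue
                raw, best = _argmax(table, cands, max_family)
                allowed |= best
        ok = opt_masks[m] <= allowed
        satisfied[m] = ok
        if not ok:
            bad.extend(
                (m, table.set_of(x)) for x in sorted(opt_masks[m] - allowed)
            )
    return GapScanReport(
        J=J,
        family=repr(fam),
        satisfied=satisfied,
        counterexamples=tuple(bad),
        optima=opt,
    )


# -- chain steps -------------------------------------------------------


def chain_step(
    net: PhyloNetwork,
    Y: OptSequence,
    p: int,
    q: int,
    fam: SwapFamily,
    table: DiversityTable | None = None,
) -> tuple[int, SwapPair] | None:
    """Realize (p, q) ≺· (p−j, q+j) on an optimal sequence.

    Takes the deterministic representatives Y_p, Y_q and returns the
    first improving pair (A, B) ∈ fam together with j = |A|−|B|.  On a
    network matching the family's class the exchange property
    guarantees a result; ``None`` is therefore a violation certificate.
    """
    if not 0 <= q < p <= len(Y) - 1:
        raise ValueError("requires 0 <= q < p <= n")
    if table is None:
        table = DiversityTable(net)
    Yp = Y[p].representative()
    Yq = Y[q].representative()
    mp, mq = table.mask_of(Yp), table.mask_of(Yq)
    lhs = table.raw(mp) + table.raw(mq)
    for pair in fam.iter_restricted(Yp - Yq, Yq - Yp):
        a = table.mask_of(pair.A)
        b = table.mask_of(pair.B)
        rhs = table.raw((mp & ~a) | b) + table.raw((mq & ~b) | a)
        if lhs <= rhs or table.raw_eq(lhs, rhs):
            return pair.j, pair
    return None
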