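# Methods

## Model and definitions

A *phylogenetic network* on a label set Σ is a rooted directed acyclic
simple graph in which every node of in-degree ≥ 2 (*reticulation*) has
out-degree exactly 1 and whose out-degree-0 nodes (*leaves*) are
bijectively labelled by Σ.  Elementary nodes (in-degree ≤ 1,
out-degree 1) are deliberately allowed; they arise naturally in
generated networks and simplify grafting constructions.  Arcs carry
nonnegative weights, interpreted as branch lengths.

For X ⊆ Σ, the ancestor closure ↑X contains every arc whose head has a
descendant leaf in X, and

    rPSD(X) = Σ_{e ∈ ↑X} w(e).

Structural classification: a *blob* is a biconnected component of the
underlying undirected graph with more than two nodes; its *split node*
is the unique blob node ancestral to all blob nodes (uniqueness is
asserted at runtime); blob reticulations with no child inside the blob
are *exit reticulations*.  The *level* is the maximum number of
reticulations per biconnected component; the *arity* the maximum
reticulation in-degree.  A reticulation is counted in the (unique)
biconnected component containing its incoming arcs — both in-arcs of a
reticulation always lie in one component, and this convention avoids
double-counting a reticulation into the trivial component of its
outgoing arc.  Level-0 networks are trees; semibinary (arity ≤ 2)
level-1 networks are galled trees.  The arity of a tree is reported as
0, so "semi-d-ary" is vacuously true on trees for every d ≥ 2.

## Exchange families and improving pairs

The families of candidate swaps are

* S_0 = {({x}, ∅)} — single-leaf moves (sufficient on trees);
* S_{1,d} = S_0 ∪ {(A,B) : A ∩ B = ∅, 1 ≤ |B| < |A| ≤ d};
* S_{k,d} (k ≥ 2) = S_0 ∪ {(A,B) : A ∩ B = ∅, 1 ≤ |B| < |A| < dk,
  |A| − |B| ≤ (d−1)k};
* S_d = S_0 ∪ {(A,{b}) : b ∉ A, 1 < |A| ≤ d} — the level-1 refinement.

A pair (A, B) with A ⊆ X∖X', B ⊆ X'∖X is *improving* for (X, X') when
rPSD(X) + rPSD(X') ≤ rPSD((X∖A)∪B) + rPSD((X'∖B)∪A).  The inequality
is non-strict by definition, so the full swap is always improving; the
content of the exchange property is that an improving pair exists
*inside the family* S_{k,d} matching the network's class.  Enumeration
order is fixed (increasing |A|, then |B|, then lexicographic), making
"first improving pair" reproducible.  The closed-form cardinality of
S_{k,d} clamps the inner summation index to |B| ≥ 1 (the set
definition requires nonempty B outside S_0) and truncates terms with
|A| > n, where the binomials vanish.

On semi-d-ary level-1 networks, an improving pair of the one-for-many
form (A, {b}) can be localized by a blob with exit reticulation H and
split node v satisfying X ∩ C(H) = ∅, b ∈ C(H), A ⊆ C(v)
(`corollary1_witness` checks exactly these three conditions).  The
localization is *not* a property of every improving pair: improving
pairs that merely tie, or that coexist with a working single-leaf
move, routinely have no such blob (empirically 473 of 35 046 improving
one-for-many pairs on 40 seeded galled trees are localized).  The
property that does hold, and that the test suite asserts, is the one
the refinement is for: whenever (X, X') admits *no* improving pair in
S_0, some improving (A, {b}) is blob-localized (273 of 273 such cases
in the same sweep).

## Optimization

Opt_m is the family of *all* size-m subsets of maximum rPSD.  All
optimizers return complete families:

* **Brute force** enumerates all C(n, m) subsets (guarded to n ≤ 20).
* **Trees**: grow every member of Opt_{m−1} by one best leaf.
* **Galled trees**: Opt_m = Opt-τ_{1,2,1}(Opt_{m−1}) — candidates are
  add-one-leaf and replace-leaf-by-pair applied to every member of
  Opt_{m−1}.  A representative mode propagates a single set per size;
  this shortcut is only proven safe on galled trees, so it is
  restricted to them.
* **Semibinary level-2 / semi-3-ary level-1**: candidates pool
  add-one, one-for-two and two-for-three from Opt_{m−1} and
  one-for-three from Opt_{m−2}; the two-for-three move is skipped on
  semi-3-ary level-1 networks, where the level-1 localization shows it
  is never needed.

The greedy engines take the argmax over the *entire* candidate pool
rather than per-member optima: the pool consists of size-m sets and
contains Opt_m by the containment results, so its argmax equals Opt_m
exactly.  Full-family propagation (not single representatives) is the
default because the containments quantify over all members of the
earlier families.

The **gap scan** tests `Opt_m ⊆ ∪_{j=1..J} Opt-τ_{k,d,j}(Opt_{m−j})`
with all optima computed by fresh brute force (never by the greedy
under test) and Opt-τ computed per the definition, as the union of
per-member expansion optima.  Violations are emitted as certificates
(network, m, witness set); on semibinary level-3 and semi-4-ary
level-1 networks none is known, and the scans here reproduce that
negative outcome on 200 seeded networks per class with 5–8 leaves and
J = 3 — sizes chosen so the whole suite runs in seconds while still
exercising every cardinality; brute force is exponential in n, which
is the binding constraint on any such search.

## Numerical policy

Weights parsed from text or produced by the generators are exact
`fractions.Fraction` values (decimal literals exactly).  The
all-subsets table rescales weights to a common integer denominator, so
subset values are integers and optima/ties are decided by exact
integer comparison — spurious tie-splitting would silently corrupt
family propagation, which is why exactness is the default.  Networks
built programmatically with float weights are supported; there,
near-ties within 1e-9 relative tolerance are grouped into the optimal
family, documented as approximate.  Tied families are capped (default
10 000 sets) with a hard error, since adversarially tied weights make
family sizes combinatorial.

## Synthetic data

The generators emulate the *combinatorial* study conditions — networks
of a requested level k and arity d with exact rational weights — not
biological realism (no coalescent, no hybridization-rate model, and
sampling is not uniform over the class).  A random binary tree is
grown by sequential leaf attachment; each blob is grafted onto a tree
arc as a d-path gall whose side nodes receive pendant leaves
(probability 0.8 each, by relocating existing leaves), and k−1
additional reticulations per blob take existing leaves as children.
Without the pendant leaves, galls degenerate to pendant cherries whose
exchange behaviour is tree-like; the pendant structure mirrors the
worked example and makes the exchange suites informative.  Weight
models: unit, uniform integers, uniform two-decimal rationals — the
mixed integer/decimal settings used in the oracle-equivalence suites
produce occasional genuine ties, exercising family propagation.
Passing tests on these networks demonstrate correctness of the
algorithms on their intended classes; they say nothing about
robustness to real-data pathologies (zero-length arcs are legal but
untested at scale, and no empirical network data is included).

The first worked-example fixture is reconstructed from its 15 known
subset-diversity values; the split of weight 1 across the three arcs
meeting its reticulation (0.5/0.3/0.2) is not identifiable from those
values — the three arcs are ancestral only to x2, so only their sum is
observable — and is fixed for determinism.  The second (the level-k
tightness witness) is wired so that the two decomposition identities
rPSD({x_1..x_k}) = Σ w(e_i) + Σ_{E_0} w(e) and
rPSD({y}) = Σ_{E_0∪E_1} w(e) hold verbatim, with the root serving as
the second parent of the first reticulation (required for all k chain
reticulations to have in-degree 2 and for the root to be binary);
these identities, checked in the tests, are the contract — any wiring
satisfying them is equivalent for every result that depends on the
fixture.

## Known limitations

* Optimization beyond the proven classes falls back to brute force
  (n ≤ 20); there is no ILP/flow solver for the general NP-hard
  problem.
* The gap scan can refute greedy-reachability on a given network but
  can never prove it for a class; absence of counterexamples at n ≤ 8
  is evidence, not proof.
* eNewick support covers single statements with the hybrid-tag
  convention (tag merging, per-occurrence branch lengths = incoming
  arc weights, missing lengths default to 1); Nexus, PhyloXML, split
  networks and multi-statement files are out of scope.
* Generated networks may contain elementary nodes; consumers requiring
  fully resolved binary networks should check `classify(...).is_binary`.
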