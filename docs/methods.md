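# Methods

## Data model

A network is a finite DAG with one root, every vertex reachable from it, no
self-loops and no parallel arcs (the arc set is a set of ordered pairs, so
duplicates collapse at build time).  Vertex identities are opaque strings
and survive every rewrite exactly as the operations dictate: contraction of
`(v', v)` deletes `v'` and keeps `v`; expansion of `w` mints the fresh id
`w__exp<k>` with the smallest free `k`.  Leaves are the outdegree-0
vertices; their labels default to the vertex id.  A single isolated vertex
is a valid network whose root is its only leaf; its one (trivial) block is
itself, its level is 0, and the vacuous structural flags (phylogenetic,
separated, ...) are all true.

Networks are immutable after validation.  The ancestor order, reflexive
descendant sets, clusters and blocks are computed once per instance and
cached; rewrites always return fresh networks.

## Blocks, shortcuts, level

Blocks are the maximal biconnected subgraphs of the underlying undirected
simple graph (networkx biconnected components).  Every block stores its
unique ⪯-maximal vertex and its ⪯-minimal (terminal) vertices; a block is
non-trivial iff it has at least three vertices.  An arc `(u, w)` is a
shortcut iff some other child of `u` is a strict ancestor of `w`, checked
against the cached descendant sets.  The level of a network is the maximum
over blocks of the number of hybrid vertices other than the block maximum —
equivalently, of hybrids *properly* contained in the block.

## Tree-basedness via matching

A spanning tree with leaf set exactly `X` arises from any choice of one
in-arc per non-root vertex; the only vertices that can degenerate into
dummy leaves are the omnians (inner vertices with only hybrid children).
The network is tree-based iff the bipartite graph of omnians versus their
children admits a matching saturating the omnians (Hall's condition on
omnian sets).  We use Hopcroft–Karp from networkx; the witness tree breaks
ties by lexicographic vertex id.  A brute-force oracle that enumerates all
parent-choice functions (capped at 2·10⁶ functions) backs this reduction in
the test suite; the matching criterion is taken as the definition for the
general networks handled here, where attachment points may have indegree
greater than one.

## Clustering systems

Clusters are frozensets of leaf labels; deterministic output (multiset
keys, file formats, caterpillar orders) uses sorted label tuples.  The
closure operator intersects all clusters containing the query; closedness
is decided by the pairwise-intersection criterion, and the intersection
closure iterates pairwise intersections to a fixpoint, which coincides with
closing under intersections of arbitrary subfamilies.  Property (L) is
evaluated in its grouped form: for each cluster, the intersections with all
of its overlap partners must coincide.  (2-Inc) is read off the cover
relation (inclusion-maximal proper sub-clusters / inclusion-minimal proper
super-clusters).  Pre-binary/binary enumerate all leaf pairs and their
minimal containing clusters, an O(|X|²·|𝒞|) cost that is irrelevant at the
instance sizes this package targets.

Pre-pyramidality (all clusters intervals of some total order): under (L) it
is equivalent to (N3O), which we use as a fast path; without (L) a
backtracking search over orders runs, pruning prefixes in which a cluster
has an internal gap or was interrupted before completion.  The search is
refused above 10 elements — without (L), no polynomial certificate is
implemented (the general forbidden-subhypergraph machinery for interval
hypergraphs is out of scope).

## Least common ancestors

`LCA(A)` is computed from the cached clusters: `v ∈ LCA(A)` iff `A ⊆ C(v)`
and no child of `v` contains `A` — the child formulation of ⪯-minimality,
checked in the suite against a plain scan over all vertices.  The
lca-network decision prefers the structural route: under PCC it equals
closedness of the clustering system; otherwise an exhaustive check over all
non-empty leaf subsets runs, permitted up to 12 leaves (4095 queries).  The
strong variant uses the weak-hierarchy equivalence, and for at most 8
leaves additionally re-verifies the pair-witness condition directly as an
internal guard.  `classify_regularity` reports a `least_resolved_candidate`
flag: under PCC, least-resolved and regular coincide, so the flag is exact
there; without PCC only the necessary condition (shortcut-free, no
outdegree-1 vertex) is reported, and the name says so.

## Rewrites and canonical constructions

`cntr` refuses shortcuts (contracting one creates a directed cycle) and
silently drops would-be parallel arcs; a leaf that acquires children loses
its label, shrinking `X` — exactly the boundary case the theory allows.
`regularize` removes all current shortcuts first, then contracts out-arcs
of outdegree-1 vertices top-down (ancestor-maximal first), re-scanning
because contraction can expose new shortcuts; the fixpoint is independent
of the order, which a randomized-schedule test confirms.  The same
reduction loop implements `least_resolved_level1` *without* the PCC gate:
for level-1 networks the loop provably reaches the unique regular network
even when the input is non-phylogenetic and violates PCC, so requiring PCC
there would wrongly reject valid inputs.

The Hasse network names non-singleton cluster vertices `{a,b,...}` (sorted
labels in braces) and singleton vertices by their label, so leaf labels
never collide with internal ids as long as taxon names avoid braces and
commas.  The cluster network expands every hybrid vertex of the Hasse
network.

Leaf-labeled isomorphism uses networkx's VF2 matcher with a node match on
leaf labels (or unconstrained for plain digraph isomorphism); instances in
this package are small (tens of vertices), where VF2's worst case is a
non-issue, so no custom canonical labeling was written.  `φ_PCC` sorts the
equal-cluster chains of both networks from the ⪯-maximal vertex downward
and maps positionally; for semi-regular inputs with equal multisets it is a
leaf-fixing graph isomorphism, which the tests verify against independently
relabeled rebuilds.

## Level-1 machinery

The overlap-block sets follow the definitions literally: `B0(C)` collects
clusters whose pairwise intersection with a partner is exactly `C`; `Top`
is the closure of their union, or — for clusters without overlap witnesses
— the unique inclusion-minimal strict superset, whose uniqueness only
closedness guarantees (a dedicated error reports the violation otherwise).
Block identification from clusters alone requires closed + (L) and is
cross-checked vertex-set-wise against the blocks of the actual Hasse
network.

The compatibility test is a direct implementation of the characterization:
test (L) in its grouped form, build the intersection closure, construct the
cluster network, and assert the witness invariants (separated,
phylogenetic, level ≤ 1, clusters equal to the closure).  No attempt is
made to meet a particular asymptotic bound; correctness, not complexity, is
the contract here, and instances are small.  The binary variant
additionally requires every hybrid of the closure's Hasse network to have
indegree exactly 2, then refines the cluster network to binary: hybrids
with outdegree ≠ 1 are expanded first, superfluous outdegree-1 tree
vertices suppressed, and every tree vertex with more than two children is
replaced by a caterpillar over its non-block children plus one slot per
cycle block rooted there (the block's two cycle children re-attach beneath
their slot).  Caterpillar order sorts children by the smallest leaf label
below them, making the output deterministic.

## Synthetic data

`gen_random_level1` grows a network top-down over the labeled leaves
`x1..xn`: each recursion step turns a leaf subset into either an ordinary
tree vertex (a random partition into parts) or an undirected cycle block —
a top with two arms meeting in one terminal hybrid, every arm vertex
carrying at least one pendant subnetwork and the hybrid exactly one.  A
capacity argument (a subtree on m leaves can host at most ⌊(m−1)/2⌋ nested
cycles) drives the block-placement pressure so that the requested number of
blocks is always met exactly, or the configuration is rejected as
infeasible up front.  Consequences of the construction, relied on by the
tests: the output is always phylogenetic, separated and tree-child; without
shortcut injection every hybrid has indegree 2 (so the output is a galled
tree), cycles have at least 4 vertices, and the network is shortcut-free;
`force_binary` restricts all partitions to two parts, which yields binary
networks; `allow_shortcuts` permits 3-cycles (whose chord from top to
hybrid is inherently a shortcut) and adds the top-to-hybrid chord to larger
cycles with probability 1/2 each.  Identical configuration and seed give
bit-identical networks.

What the generator does *not* emulate: non-separated networks, hybrids
with indegree above 3, networks violating tree-childness or PCC, level-2+
structure, or any natural (e.g. birth–death) distribution over shapes — the
attachment scheme is a convenience distribution.  Tests that need such
shapes use the hand-built fixtures (the rooted K₂,₂, the shortcut
triangle, the complete-bipartite level-k construction) instead; passing
property suites therefore demonstrate correctness of the calculus on the
classes covered, not statistical claims about real reticulation histories.

`enumerate_small_networks` exhaustively enumerates phylogenetic
quasi-binary level-1 networks on up to 4 labeled leaves by the same
grammar (tree vertices / cycle blocks with pendant subnetworks, arms of
length ≥ 0 on one side so that shortcut triangles are included), deduplated
up to leaf-fixing isomorphism within equal-multiset groups.  The encoding
and uniqueness statements exercised on it all live inside this universe;
it makes no claim to enumerate unrestricted DAGs.

## Problem sizes and numerics

Everything here is exact set/graph combinatorics — no floating point, no
tolerances.  The study conditions use networks of 4–9 leaves with 0–3
cycle blocks (matching the scale of the worked examples the theory is
illustrated on): 500 networks for the characterization round trips, 200
systems for the multiplicity law, 500 instances for the tree-based oracle
agreement, all 2ⁿ−1 lca queries per network up to 6 leaves, 1000 systems
(half mutated to break (L)) for the compatibility decision, and complete
enumeration (884 networks) on four leaves for the multiset-encoding check.
The whole suite runs in a few seconds.

## Known limitations

* `is_lca_network` has no decision route for networks that violate PCC and
  have more than 12 leaves.
* Pre-pyramidality without (L) is exponential and capped at 10 elements.
* The enumeration universe is quasi-binary level-1 only.
* Whether cluster overlaps suffice to identify the non-trivial blocks of
  general semi-regular (rather than level-1) networks is an open question;
  the package exposes the level-1 machinery only under its proven
  preconditions.
* Softwired cluster semantics and level-k compatibility for k ≥ 2 are out
  of scope.
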