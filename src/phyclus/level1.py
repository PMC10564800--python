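"""Level-1 theory: reading blocks off a clustering system, the closed + (L)
characterization, compatibility testing, and the galled / binary subclasses.

For a cluster C of a clustering system, the *overlap-block sets* identify the
non-trivial block of the Hasse diagram whose hybrid vertex is C:

B0(C)    clusters C' (other than C) that intersect some partner C'' in
         exactly C -- the prospective block interior
U(C)     the union of B0(C)
Top(C)   cl(U(C)) when B0(C) is non-empty; for other clusters the unique
         inclusion-minimal strict superset (X for C = X) -- the block maximum
B(C)     B0(C) together with C and Top(C) -- the block's vertex set
D(C), Dbar(C)  the clusters strictly below C, and those not below C; together
         with C they partition the system

The central theorem implemented here: a clustering system is the cluster
system of a level-1 network iff it is closed and satisfies (L); adding (N3O)
characterizes galled trees, adding (2-Inc) characterizes binary level-1
networks.  Compatibility (is the input *contained* in the clusters of a
level-1 network?) reduces to property (L) alone, with the witness network
built as the cluster network of the intersection closure.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .clusters import (
    Cluster,
    ClusteringSystem,
    clustering_system,
    overlap,
)
from .errors import (
    HybridIndegreeTooHigh,
    NotACluster,
    NotClosedForTop,
    NotLevel1,
    PreconditionViolated,
)
from .network import Network, VertexId
from .transform import (
    _reduce,
    cluster_network_of,
    expd,
    hasse,
    phylo_reduce,
)

ClusterSet = FrozenSet[Cluster]


@dataclass(frozen=True)
class OverlapBlockSets:
    cluster: Cluster
    b0: ClusterSet
    u_set: Cluster
    top: Cluster
    bcal: ClusterSet
    d: ClusterSet
    dbar: ClusterSet


def overlap_block_sets(cs: ClusteringSystem, c) -> OverlapBlockSets:
    """Compute B0, U, Top, B, D and Dbar for a cluster of ``cs``.

    Top of a cluster with empty B0 requires a unique inclusion-minimal strict
    superset; closedness guarantees one, otherwise NotClosedForTop is raised.
    """
    c = frozenset(c)
    if c not in cs.clusters:
        raise NotACluster(f"{sorted(c)} is not a cluster of the system")
    others = [d for d in cs.clusters if d != c]
    b0: Set[Cluster] = set()
    for c1, c2 in itertools.combinations(others, 2):
        if c1 & c2 == c and overlap(c1, c2):
            b0.add(c1)
            b0.add(c2)
    u = frozenset(set().union(*b0)) if b0 else frozenset()
    if b0:
        top = cs.closure_of(u)
    elif c == cs.X:
        top = cs.X
    else:
        supersets = [d for d in cs.clusters if c < d]
        minimal = [d for d in supersets if not any(e < d for e in supersets)]
        if len(minimal) != 1:
            raise NotClosedForTop(
                f"no unique inclusion-minimal strict superset of {sorted(c)}; "
                "the system is not closed"
            )
        top = minimal[0]
    bcal = frozenset(b0 | {c, top})
    d_below = frozenset(d for d in cs.clusters if d < c)
    dbar = frozenset(d for d in cs.clusters if not d <= c)
    return OverlapBlockSets(c, frozenset(b0), u, top, bcal, d_below, dbar)


def level1_blocks_from_clusters(cs: ClusteringSystem) -> List[ClusterSet]:
    """The block vertex sets of the Hasse diagram of a closed system with
    property (L), computed purely from the clusters: B(C) is a non-trivial
    block whenever B0(C) is non-empty, and {Top(C), C} is a trivial block
    (a cut arc) for every other non-overlapping cluster C != X."""
    if not (cs.is_closed() and cs.satisfies_L()):
        raise PreconditionViolated(
            "block identification from clusters needs a closed system "
            "satisfying (L)"
        )
    if len(cs.X) == 1:
        return [frozenset({cs.X})]
    blocks: List[ClusterSet] = []
    for c in cs.clusters:
        obs = overlap_block_sets(cs, c)
        if obs.b0:
            blocks.append(obs.bcal)
        elif c != cs.X and not cs.overlap_partners(c):
            blocks.append(frozenset({obs.top, c}))
    return blocks


def is_level1_system(cs: ClusteringSystem) -> bool:
    """Exactly the clustering systems of level-1 networks."""
    return cs.is_closed() and cs.satisfies_L()


def is_galled_system(cs: ClusteringSystem) -> bool:
    """Exactly the clustering systems of galled trees."""
    return is_level1_system(cs) and cs.satisfies_n3o()


def is_binary_l1_system(cs: ClusteringSystem) -> bool:
    """Exactly the clustering systems of binary level-1 networks."""
    return is_level1_system(cs) and cs.satisfies_two_inc()


@dataclass(frozen=True)
class CompatibilityResult:
    compatible: bool
    network: Optional[Network]
    reason: str
    n_clusters_added: int


def check_l1_compatibility(cs: ClusteringSystem) -> CompatibilityResult:
    """Is there a separated phylogenetic level-1 network whose clusters
    contain ``cs``?  Equivalent to property (L).  The witness is the cluster
    network of the intersection closure I(cs); its clustering system equals
    I(cs) exactly."""
    if not cs.satisfies_L():
        return CompatibilityResult(False, None, "property (L) fails", 0)
    closure = cs.intersection_closure()
    net = cluster_network_of(closure)
    assert net.level() <= 1, "witness must be level-1"
    assert net.is_separated() and net.is_phylogenetic()
    assert clustering_system(net) == closure
    return CompatibilityResult(
        True, net, "closed under (L)", len(closure) - len(cs)
    )


def binary_l1_compatible(cs: ClusteringSystem) -> CompatibilityResult:
    """Is there a *binary* level-1 network whose clusters contain ``cs``?
    Requires (L) and that every hybrid vertex of the Hasse diagram of the
    intersection closure has indegree exactly 2; the witness is the cluster
    network of the closure, caterpillar-refined to binary."""
    if not cs.satisfies_L():
        return CompatibilityResult(False, None, "property (L) fails", 0)
    closure = cs.intersection_closure()
    h = hasse(closure)
    bad = [w for w in h.hybrids if h.indeg(w) != 2]
    if bad:
        return CompatibilityResult(
            False,
            None,
            f"hybrid vertices with indegree > 2 in the Hasse diagram: "
            f"{sorted(bad)}",
            len(closure) - len(cs),
        )
    net = resolve_to_binary(cluster_network_of(closure))
    assert net.is_binary() and net.level() <= 1
    assert cs.clusters <= clustering_system(net).clusters
    return CompatibilityResult(
        True, net, "closed under (L), hybrid indegrees 2",
        len(closure) - len(cs),
    )


def resolve_to_binary(n: Network) -> Network:
    """Refine a level-1 network whose hybrid vertices all have indegree 2
    into a binary level-1 network with a superset of its clusters.

    High-outdegree hybrids are expanded first; superfluous outdegree-1 tree
    vertices are suppressed; then every tree vertex with more than two
    children is replaced by a caterpillar over its non-block children plus
    one slot per non-trivial block rooted there, with each block's two cycle
    children re-attached beneath their slot.  Caterpillar order is by the
    smallest leaf label below each child (deterministic).
    """
    bad = [w for w in n.hybrids if n.indeg(w) != 2]
    if bad:
        raise HybridIndegreeTooHigh(
            f"hybrid vertices with indegree > 2: {sorted(bad)}"
        )
    if n.level() > 1:
        raise NotLevel1("resolve_to_binary requires a level-1 network")
    # 1) hybrids must end up with outdegree 1
    for w in sorted(n.hybrids):
        if n.outdeg(w) != 1:
            n = expd(n, w)
    # 2) suppress outdegree-1 tree vertices
    n = phylo_reduce(n)
    # 3) caterpillar resolution of high-outdegree tree vertices
    for v in sorted(n.vertices):
        if v not in n.vertices or n.is_hybrid(v) or n.outdeg(v) <= 2:
            continue
        n = _resolve_vertex(n, v)
    assert n.is_binary(), "refinement must end binary"
    return n


def _resolve_vertex(n: Network, v: VertexId) -> Network:
    g = n.copy_graph()
    block_children: Dict[int, Tuple[VertexId, ...]] = {}
    in_block: Set[VertexId] = set()
    for i, b in enumerate(n.nontrivial_blocks()):
        if b.max_vertex == v:
            kids = tuple(sorted(c for c in n.children(v) if c in b.vertices))
            block_children[i] = kids
            in_block.update(kids)
    free = [c for c in n.children(v) if c not in in_block]

    def group_key(item):
        kind, payload = item
        if kind == "free":
            return (min(n.cluster(payload)), payload)
        leafs = set()
        for c in block_children[payload]:
            leafs |= n.cluster(c)
        return (min(leafs), str(payload))

    groups = [("free", c) for c in free] + [
        ("block", i) for i in block_children
    ]
    groups.sort(key=group_key)
    assert len(groups) >= 2

    counter = itertools.count(1)

    def fresh(base: str) -> VertexId:
        while True:
            cand = f"{base}__cat{next(counter)}"
            if cand not in g:
                return cand

    def attach(parent: VertexId, item) -> None:
        kind, payload = item
        if kind == "free":
            g.add_edge(parent, payload)
        else:
            slot = fresh(v)
            g.add_edge(parent, slot)
            for c in block_children[payload]:
                g.add_edge(slot, c)

    for c in n.children(v):
        g.remove_edge(v, c)
    spine = v
    for item in groups[:-2]:
        attach(spine, item)
        nxt = fresh(v)
        g.add_edge(spine, nxt)
        spine = nxt
    attach(spine, groups[-2])
    attach(spine, groups[-1])
    return Network(g, n.leaf_labels)


def least_resolved_level1(n: Network) -> Network:
    """The unique regular (equivalently, least-resolved) level-1 network with
    the same clustering system, obtained by exhausting shortcut removal and
    outdegree-1 contraction."""
    if n.level() > 1:
        raise NotLevel1("least_resolved_level1 requires a level-1 network")
    return _reduce(n)
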