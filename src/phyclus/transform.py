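"""Graph rewrites and canonical constructions.

The calculus rests on two local rewrites and their combinations:

expd(w)      insert a fresh vertex w' above w that takes over all of w's
             in-arcs (clusters are preserved; the inverse of cntr(w', w))
cntr(v', v)  contract the non-shortcut arc (v', v): delete v' and re-attach
             its other in/out arcs to v (contracting a shortcut would create
             a directed cycle and is refused)
phylo        contract arcs below outdegree-1, indegree<=1 vertices until the
             network is phylogenetic
shortcut removal  deletes a shortcut arc; clusters and ancestor relation are
             untouched

On top of these sit the canonical constructions: the Hasse diagram of a
clustering system is the unique *regular* network with those clusters;
expanding all its hybrid vertices yields the unique *cluster network*
(semi-regular, separated, phylogenetic).  ``regularize`` reduces any PCC
network to the regular one by exhausting shortcut removal and
outdegree-1 contraction; the result is order-independent.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

import networkx as nx
from networkx.algorithms.isomorphism import DiGraphMatcher

from .clusters import (
    Cluster,
    ClusteringSystem,
    cluster_multiset,
    clustering_system,
    _key,
)
from .errors import (
    MultisetMismatch,
    NotAShortcut,
    PccViolation,
    ShortcutContraction,
    UnknownArc,
    UnknownVertex,
)
from .lca import is_pcc
from .network import Arc, Network, VertexId


@dataclass(frozen=True)
class VertexBijection:
    """A bijection between the vertex sets of two networks."""

    mapping: Tuple[Tuple[VertexId, VertexId], ...]
    fixes_leaves: bool

    @classmethod
    def from_dict(cls, d: Dict[VertexId, VertexId], fixes_leaves: bool):
        return cls(tuple(sorted(d.items())), fixes_leaves)

    def as_dict(self) -> Dict[VertexId, VertexId]:
        return dict(self.mapping)

    def __getitem__(self, v: VertexId) -> VertexId:
        return self.as_dict()[v]

    def is_graph_isomorphism(self, n1: Network, n2: Network) -> bool:
        m = self.as_dict()
        if set(m) != n1.vertices or set(m.values()) != n2.vertices:
            return False
        return {(m[u], m[v]) for u, v in n1.arcs} == n2.arcs


# --- elementary rewrites ------------------------------------------------------
def _fresh_id(n: Network, w: VertexId) -> VertexId:
    k = 1
    while f"{w}__exp{k}" in n.vertices:
        k += 1
    return f"{w}__exp{k}"


def expd(n: Network, w: VertexId) -> Network:
    """Arc expansion at w: a fresh vertex w' inherits w's in-arcs and the arc
    (w', w) is added.  Clusters, ancestor order on old vertices, level and
    shortcut-freeness are all preserved."""
    n._check_vertex(w)
    g = n.copy_graph()
    w2 = _fresh_id(n, w)
    for p in list(g.predecessors(w)):
        g.remove_edge(p, w)
        g.add_edge(p, w2)
    g.add_edge(w2, w)
    return Network(g, n.leaf_labels)


def cntr(n: Network, arc: Arc) -> Network:
    """Contract the non-shortcut arc (v', v): v' is deleted, its remaining
    in-arcs are re-attached to v and its remaining out-arcs move to v
    (would-be parallel arcs are dropped silently).  The leaf set is X or, if
    a leaf v acquires children this way, X minus that leaf."""
    n._check_arc(arc)
    if n.is_shortcut(arc):
        raise ShortcutContraction(
            f"contracting the shortcut {arc!r} would create a directed cycle"
        )
    v2, v = arc
    g = n.copy_graph()
    for u in list(g.predecessors(v2)):
        if not g.has_edge(u, v) and u != v:
            g.add_edge(u, v)
    for w in list(g.successors(v2)):
        if w != v and not g.has_edge(v, w):
            g.add_edge(v, w)
    g.remove_node(v2)
    leaves = {x for x in g if g.out_degree(x) == 0}
    labels = {x: lab for x, lab in n.leaf_labels.items() if x in leaves}
    return Network(g, labels)


def phylo_reduce(n: Network) -> Network:
    """Contract (u, w) for vertices u with outdegree 1 and indegree <= 1
    until none remains; the result is phylogenetic and has the same
    clustering system.  Candidates are processed in lexicographic order of
    the suppressed vertex (the fixpoint is unique anyway)."""
    current = n
    while True:
        cands = sorted(
            u
            for u in current.vertices
            if current.outdeg(u) == 1 and current.indeg(u) <= 1
        )
        if not cands:
            return current
        u = cands[0]
        (w,) = current.children(u)
        current = cntr(current, (u, w))


def cntr_star(n: Network, arc: Arc) -> Network:
    """cntr followed by phylo: contract a non-shortcut arc, then suppress any
    superfluous vertices the contraction exposed."""
    return phylo_reduce(cntr(n, arc))


def remove_shortcut(n: Network, arc: Arc) -> Network:
    """Delete a shortcut arc.  Vertex set, per-vertex clusters and the
    ancestor relation are unchanged."""
    n._check_arc(arc)
    if not n.is_shortcut(arc):
        raise NotAShortcut(f"{arc!r} is not a shortcut")
    g = n.copy_graph()
    g.remove_edge(*arc)
    return Network(g, n.leaf_labels)


# --- canonical constructions --------------------------------------------------
def _cluster_vertex_id(c: Cluster) -> VertexId:
    if len(c) == 1:
        (x,) = c
        return x
    return "{" + ",".join(_key(c)) + "}"


def hasse(cs: ClusteringSystem) -> Network:
    """The unique regular network of a clustering system: vertices are the
    clusters, arcs the cover relation of set inclusion, and singleton
    clusters are relabeled by their element so that the leaves carry X.  The
    result is shortcut-free, satisfies PCC, has no outdegree-1 vertex, and
    its clustering system is the input."""
    ids = {c: _cluster_vertex_id(c) for c in cs.clusters}
    g = nx.DiGraph()
    g.add_nodes_from(ids.values())
    for c in cs.clusters:
        for child in cs.cover_children(c):
            g.add_edge(ids[c], ids[child])
    labels = {ids[frozenset({x})]: x for x in cs.X}
    return Network(g, labels)


def _reduce(n: Network) -> Network:
    """Exhaust shortcut removal and contraction of out-arcs of outdegree-1
    vertices.  Shortcuts are removed first, then outdegree-1 vertices are
    contracted top-down; contraction can expose new shortcuts, so the loop
    re-scans until neither operation applies."""
    current = n
    while True:
        sc = sorted(current.shortcuts())
        if sc:
            current = remove_shortcut(current, sc[0])
            continue
        cands = [u for u in current.vertices if current.outdeg(u) == 1]
        if not cands:
            return current
        # top-down: contract an ancestor-maximal candidate first
        order = {v: i for i, v in enumerate(current._topo)}
        u = min(cands, key=lambda v: (order[v], v))
        (w,) = current.children(u)
        current = cntr(current, (u, w))


def regularize(n: Network) -> Network:
    """Reduce a PCC network to the unique regular network of its clustering
    system (isomorphic to the Hasse diagram).  The operation order does not
    affect the result."""
    if not is_pcc(n):
        raise PccViolation("regularize requires the PCC property")
    return _reduce(n)


def cluster_network_of(cs: ClusteringSystem) -> Network:
    """The unique cluster network (semi-regular, separated, phylogenetic)
    with clustering system ``cs``: the Hasse diagram with every hybrid vertex
    expanded."""
    net = hasse(cs)
    for w in sorted(net.hybrids):
        net = expd(net, w)
    return net


# --- isomorphism --------------------------------------------------------------
def isomorphic(
    n1: Network, n2: Network, fix_leaves: bool = True
) -> Optional[VertexBijection]:
    """Decide graph isomorphism; with ``fix_leaves`` every leaf must map to
    the equally labeled leaf (the relation written N1 ~= N2), without it any
    digraph isomorphism counts (N1 ~ N2).  Returns a witness bijection or
    None."""
    g1, g2 = n1.copy_graph(), n2.copy_graph()
    if fix_leaves:
        if n1.labels != n2.labels:
            return None
        for g, net in ((g1, n1), (g2, n2)):
            for v in g:
                g.nodes[v]["tag"] = net.leaf_labels.get(v)
        matcher = DiGraphMatcher(
            g1, g2, node_match=lambda a, b: a["tag"] == b["tag"]
        )
    else:
        matcher = DiGraphMatcher(g1, g2)
    if not matcher.is_isomorphic():
        return None
    return VertexBijection.from_dict(dict(matcher.mapping), fix_leaves)


# --- the PCC map --------------------------------------------------------------
def _chains_by_cluster(n: Network) -> Dict[Cluster, List[VertexId]]:
    chains: Dict[Cluster, List[VertexId]] = {}
    for v in n.vertices:
        chains.setdefault(n.cluster(v), []).append(v)
    for c, vs in chains.items():
        # under PCC the vertices with a common cluster are totally ordered;
        # sort from the ancestor-maximal vertex downward
        depth = {v: sum(1 for w in vs if n.descends(w, v)) for v in vs}
        vs.sort(key=depth.__getitem__, reverse=True)
    return chains


def phi_pcc(n: Network, other: Network) -> VertexBijection:
    """The canonical vertex bijection between two PCC networks with equal
    cluster multisets: per cluster, the order-sorted chains are mapped
    positionally.  For semi-regular networks this map is a leaf-fixing graph
    isomorphism."""
    if not is_pcc(n) or not is_pcc(other):
        raise PccViolation("phi_pcc requires both networks to satisfy PCC")
    if cluster_multiset(n) != cluster_multiset(other):
        raise MultisetMismatch("cluster multisets differ")
    chains1 = _chains_by_cluster(n)
    chains2 = _chains_by_cluster(other)
    mapping: Dict[VertexId, VertexId] = {}
    for c, vs in chains1.items():
        for v, w in zip(vs, chains2[c]):
            mapping[v] = w
    fixes = all(
        other.leaf_labels.get(mapping[v]) == lab
        for v, lab in n.leaf_labels.items()
    )
    return VertexBijection.from_dict(mapping, fixes)
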