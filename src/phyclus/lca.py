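"""Least common ancestors in rooted networks, and the regularity ladder.

In a DAG the set LCA(A) of ancestor-minimal common ancestors of a leaf set A
is non-empty (the root is a common ancestor) but need not be a singleton.
The properties studied here grade how well-behaved the lca is:

(CL)                 lca(C(v)) is unique for every vertex v
lca-network          lca(A) is unique for every non-empty A subseteq X
strong lca-network   additionally every lca(A) is witnessed by a leaf pair
(PCC)                order-comparability of vertices coincides with
                     nestedness of their clusters

Key facts wired into the implementations: PCC implies CL; a PCC network is an
lca-network iff its clustering system is closed; an lca-network is strong iff
its clustering system is a weak hierarchy.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List

from .clusters import clustering_system
from .errors import (
    EmptyQuery,
    GroundSetTooLarge,
    NotSemiRegular,
    UnknownLeaf,
)
from .network import Network, VertexId


@dataclass(frozen=True)
class LcaResult:
    query: FrozenSet[str]
    lca_set: FrozenSet[VertexId]
    unique: bool

    @property
    def vertex(self) -> VertexId:
        if not self.unique:
            raise ValueError("lca is not unique")
        (v,) = self.lca_set
        return v


def lca_set(n: Network, a: Iterable[str]) -> LcaResult:
    """All ancestor-minimal common ancestors of the leaves labeled by ``a``.

    A vertex v is in LCA(A) iff A is contained in C(v) and A is contained in
    no child's cluster (the child formulation of minimality).
    """
    query = frozenset(str(x) for x in a)
    if not query:
        raise EmptyQuery("lca of the empty leaf set is undefined")
    unknown = query - n.labels
    if unknown:
        raise UnknownLeaf(f"unknown leaf labels: {sorted(unknown)}")
    result = {
        v
        for v in n.vertices
        if query <= n.cluster(v)
        and not any(query <= n.cluster(c) for c in n.children(v))
    }
    return LcaResult(query, frozenset(result), len(result) == 1)


def has_CL(n: Network) -> bool:
    """Cluster-lca property: lca(C(v)) is unique for every vertex.

    When true, the consequences lca(C(v)) <= v and C(lca(C(v))) = C(v) are
    asserted as internal sanity checks.
    """
    for v in n.vertices:
        res = lca_set(n, n.cluster(v))
        if not res.unique:
            return False
        q = res.vertex
        assert n.descends(q, v), "lca(C(v)) must descend from v"
        assert n.cluster(q) == n.cluster(v), "lca(C(v)) must carry C(v)"
    return True


def is_pcc(n: Network) -> bool:
    """Path-cluster comparability: for all u, v the order comparability of u
    and v is equivalent to the nestedness of C(u) and C(v)."""
    vs = sorted(n.vertices)
    for u, v in itertools.combinations(vs, 2):
        cu, cv = n.cluster(u), n.cluster(v)
        nested = cu <= cv or cv <= cu
        if n.comparable(u, v) != nested:
            return False
    return True


_EXHAUSTIVE_LIMIT = 12


def is_lca_network(n: Network, report_route: bool = False):
    """Unique lca(A) for every non-empty subset A of X.

    Route 1 (preferred): if the network satisfies PCC, this is equivalent to
    closedness of its clustering system.  Route 2: exhaustive check over all
    2^|X| - 1 queries, permitted for |X| <= 12.
    """
    if is_pcc(n):
        verdict = clustering_system(n).is_closed()
        route = "pcc-closedness"
    elif len(n.labels) <= _EXHAUSTIVE_LIMIT:
        verdict = _lca_exhaustive(n)
        route = "exhaustive"
    else:
        raise GroundSetTooLarge(
            f"|X| = {len(n.labels)} > {_EXHAUSTIVE_LIMIT} and PCC fails; "
            "no decision route applies"
        )
    return (verdict, route) if report_route else verdict


def _lca_exhaustive(n: Network) -> bool:
    labels = sorted(n.labels)
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            if not lca_set(n, combo).unique:
                return False
    return True


def is_strong_lca_network(n: Network) -> bool:
    """lca-network in which every lca(A) equals lca({x, y}) for some pair of
    leaves x, y in A.

    Equivalent to: lca-network with a weak-hierarchy clustering system.  For
    |X| <= 8 the pair-witness condition is additionally verified directly, as
    a guard on that equivalence.
    """
    if not is_lca_network(n):
        return False
    weak = clustering_system(n).is_weak_hierarchy()
    if len(n.labels) <= 8:
        direct = _strong_lca_direct(n)
        assert direct == weak, (
            "weak-hierarchy shortcut disagrees with the direct pair-witness "
            "check"
        )
        return direct
    return weak


def _strong_lca_direct(n: Network) -> bool:
    labels = sorted(n.labels)
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            target = lca_set(n, combo).vertex
            if not any(
                lca_set(n, {x, y}).vertex == target
                for x, y in itertools.combinations_with_replacement(combo, 2)
            ):
                return False
    return True


@dataclass(frozen=True)
class RegularityRecord:
    semi_regular: bool
    regular: bool
    cluster_network: bool
    least_resolved_candidate: bool


def classify_regularity(n: Network) -> RegularityRecord:
    """The regularity ladder.

    semi-regular     shortcut-free and PCC
    regular          semi-regular with no outdegree-1 vertex (equivalently,
                     order-isomorphic to the Hasse diagram of its clusters)
    cluster network  semi-regular, separated and phylogenetic

    ``least_resolved_candidate``: under PCC, least-resolved coincides with
    regular; without PCC only the necessary condition (shortcut-free, no
    outdegree-1 vertex) is reported.
    """
    pcc = is_pcc(n)
    sf = n.is_shortcut_free()
    semi = sf and pcc
    no_out1 = not any(n.outdeg(v) == 1 for v in n.vertices)
    regular = semi and no_out1
    cluster_net = semi and n.is_separated() and n.is_phylogenetic()
    candidate = regular if pcc else (sf and no_out1)
    return RegularityRecord(semi, regular, cluster_net, candidate)


def q_path(n: Network, u: VertexId) -> List[VertexId]:
    """Q(u): all vertices sharing the cluster C(u), returned from the
    ancestor-maximal to the minimal one.  In a semi-regular network these lie
    consecutively along an induced directed path, which is asserted."""
    rec = classify_regularity(n)
    if not rec.semi_regular:
        raise NotSemiRegular("q_path requires a semi-regular network")
    c = n.cluster(u)
    q = [v for v in n.vertices if n.cluster(v) == c]
    # totally ordered by <= thanks to PCC; sort descending
    depth = {v: sum(1 for w in q if n.descends(w, v)) for v in q}
    q.sort(key=depth.__getitem__, reverse=True)
    for a, b in zip(q, q[1:]):
        assert (a, b) in n.arcs, "Q(u) must form a directed path"
    return q
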