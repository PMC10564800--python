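"""Hardwired clusters and clustering systems.

The cluster of a vertex v is C(v), the set of leaf labels reachable from v.
A *clustering system* on X is a family of non-empty subsets of X containing X
itself and every singleton.  This module houses the set- and multiset-valued
views of a network's clusters, the closure operator cl(A) = intersection of
all clusters containing A, the intersection closure, and the whole battery of
set-system predicates used to characterize network classes:

hierarchy            no two clusters overlap
closed               all non-empty pairwise intersections are clusters
pre-binary / binary  unique minimal cluster per leaf pair (binary: and each
                     cluster is such a minimal container)
weak hierarchy       triple intersections reduce to a pairwise one
(L)                  a cluster meets all of its overlap partners in one set
(N3O)                no three pairwise overlapping clusters
paired hierarchy     each cluster overlaps at most one other
(2-Inc)              at most two cover-children and two cover-parents each

Clusters are frozensets of leaf labels; anywhere a deterministic order is
needed they are keyed by their sorted label tuple.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from functools import cached_property
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

from .errors import (
    GroundSetTooLargeWithoutL,
    InvalidClusteringSystem,
    NotSubsetOfGroundSet,
    UnknownVertex,
)
from .network import Network, VertexId

Cluster = FrozenSet[str]


def _key(c: Iterable[str]) -> Tuple[str, ...]:
    return tuple(sorted(c))


def overlap(a: Cluster, b: Cluster) -> bool:
    """Two sets overlap if they intersect but neither contains the other."""
    inter = a & b
    return bool(inter) and inter != a and inter != b


class ClusteringSystem:
    """A set of clusters over a ground set X, validated against the axioms:
    no empty cluster, X present, every singleton present."""

    def __init__(self, ground_set: Iterable[str], clusters: Iterable[Iterable[str]]):
        self.X: Cluster = frozenset(str(x) for x in ground_set)
        self.clusters: FrozenSet[Cluster] = frozenset(
            frozenset(str(x) for x in c) for c in clusters
        )
        self._validate()

    def _validate(self) -> None:
        if not self.X:
            raise InvalidClusteringSystem("ground set must be non-empty")
        if frozenset() in self.clusters:
            raise InvalidClusteringSystem("empty set is not a cluster")
        if self.X not in self.clusters:
            raise InvalidClusteringSystem("ground set X must be a cluster")
        for x in self.X:
            if frozenset({x}) not in self.clusters:
                raise InvalidClusteringSystem(f"singleton {{{x}}} missing")
        for c in self.clusters:
            if not c <= self.X:
                raise InvalidClusteringSystem(
                    f"cluster {sorted(c)} is not a subset of X"
                )

    @classmethod
    def complete(cls, ground_set: Iterable[str], extra: Iterable[Iterable[str]] = ()):
        """Build a system from arbitrary non-empty subsets, auto-adding X and
        the singletons (read-time convenience; strict mode is __init__)."""
        X = frozenset(str(x) for x in ground_set)
        cl = {frozenset(str(x) for x in c) for c in extra}
        cl.discard(frozenset())
        cl.add(X)
        cl |= {frozenset({x}) for x in X}
        return cls(X, cl)

    # -- container protocol ----------------------------------------------------
    def __contains__(self, c: Iterable[str]) -> bool:
        return frozenset(c) in self.clusters

    def __iter__(self):
        return iter(sorted(self.clusters, key=_key))

    def __len__(self) -> int:
        return len(self.clusters)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ClusteringSystem)
            and self.X == other.X
            and self.clusters == other.clusters
        )

    def __hash__(self) -> int:
        return hash((self.X, self.clusters))

    def __repr__(self) -> str:
        inner = ", ".join("{" + ",".join(_key(c)) + "}" for c in self)
        return f"ClusteringSystem(X={{{','.join(sorted(self.X))}}}, {inner})"

    # -- closure ---------------------------------------------------------------
    def closure_of(self, a: Iterable[str]) -> Cluster:
        """cl(A): intersection of all clusters containing A (X always
        qualifies).  Enlarging, isotone, idempotent; cl(empty) = empty for
        |X| > 1."""
        a = frozenset(str(x) for x in a)
        if not a <= self.X:
            raise NotSubsetOfGroundSet(
                f"{sorted(a - self.X)} not in the ground set"
            )
        result = set(self.X)
        for c in self.clusters:
            if a <= c:
                result &= c
        return frozenset(result)

    def is_closed(self) -> bool:
        """Closedness via the pairwise criterion: every non-empty
        intersection of two clusters is itself a cluster."""
        cs = list(self.clusters)
        for i, a in enumerate(cs):
            for b in cs[i + 1:]:
                inter = a & b
                if inter and inter not in self.clusters:
                    return False
        return True

    def intersection_closure(self) -> "ClusteringSystem":
        """The least closed superset I(C), built by iterating pairwise
        non-empty intersections to a fixpoint (equivalent to closing under
        intersections of arbitrary subfamilies)."""
        current: Set[Cluster] = set(self.clusters)
        frontier = list(current)
        while frontier:
            new: Set[Cluster] = set()
            for a in frontier:
                for b in current:
                    inter = a & b
                    if inter and inter not in current and inter not in new:
                        new.add(inter)
            current |= new
            frontier = list(new)
        return ClusteringSystem(self.X, current)

    # -- overlap structure -----------------------------------------------------
    @cached_property
    def _overlap_partners(self) -> Dict[Cluster, List[Cluster]]:
        partners: Dict[Cluster, List[Cluster]] = {c: [] for c in self.clusters}
        cs = list(self.clusters)
        for i, a in enumerate(cs):
            for b in cs[i + 1:]:
                if overlap(a, b):
                    partners[a].append(b)
                    partners[b].append(a)
        return partners

    def overlap_partners(self, c: Cluster) -> List[Cluster]:
        return list(self._overlap_partners[frozenset(c)])

    # -- predicates ------------------------------------------------------------
    def is_hierarchy(self) -> bool:
        return all(not p for p in self._overlap_partners.values())

    def satisfies_L(self) -> bool:
        """(L): for every cluster C1, the intersections with all of its
        overlap partners coincide (grouped form of the definition)."""
        for c, partners in self._overlap_partners.items():
            if len(partners) >= 2:
                first = c & partners[0]
                if any(c & p != first for p in partners[1:]):
                    return False
        return True

    def satisfies_n3o(self) -> bool:
        """No three distinct pairwise overlapping clusters."""
        for c, partners in self._overlap_partners.items():
            for a, b in itertools.combinations(partners, 2):
                if overlap(a, b):
                    return False
        return True

    def is_paired_hierarchy(self) -> bool:
        return all(len(p) <= 1 for p in self._overlap_partners.values())

    def is_weak_hierarchy(self) -> bool:
        """C1 & C2 & C3 is always one of the pairwise intersections."""
        cs = list(self.clusters)
        for a, b, c in itertools.combinations(cs, 3):
            triple = a & b & c
            if triple not in (a & b, a & c, b & c):
                return False
        return True

    def _min_containers(self, pair: Cluster) -> List[Cluster]:
        containing = [c for c in self.clusters if pair <= c]
        return [
            c for c in containing
            if not any(d < c for d in containing)
        ]

    def is_pre_binary(self) -> bool:
        for x, y in itertools.combinations_with_replacement(sorted(self.X), 2):
            if len(self._min_containers(frozenset({x, y}))) != 1:
                return False
        return True

    def is_binary(self) -> bool:
        if not self.is_pre_binary():
            return False
        witnessed = set()
        for x, y in itertools.combinations_with_replacement(sorted(self.X), 2):
            (c,) = self._min_containers(frozenset({x, y}))
            witnessed.add(c)
        return witnessed == set(self.clusters)

    # -- Hasse cover relation ---------------------------------------------------
    @cached_property
    def _cover_children(self) -> Dict[Cluster, List[Cluster]]:
        """children[C] = inclusion-maximal proper sub-clusters of C."""
        children: Dict[Cluster, List[Cluster]] = {c: [] for c in self.clusters}
        for c in self.clusters:
            subs = [d for d in self.clusters if d < c]
            children[c] = [
                d for d in subs if not any(d < e for e in subs)
            ]
        return children

    def cover_children(self, c: Cluster) -> List[Cluster]:
        return list(self._cover_children[frozenset(c)])

    def cover_parents(self, c: Cluster) -> List[Cluster]:
        c = frozenset(c)
        return [d for d, kids in self._cover_children.items() if c in kids]

    def satisfies_two_inc(self) -> bool:
        for c in self.clusters:
            if len(self._cover_children[c]) > 2:
                return False
            if len(self.cover_parents(c)) > 2:
                return False
        return True

    def flags(self) -> "CsFlags":
        return CsFlags(
            hierarchy=self.is_hierarchy(),
            pre_binary=self.is_pre_binary(),
            binary=self.is_binary(),
            weak_hierarchy=self.is_weak_hierarchy(),
            property_L=self.satisfies_L(),
            n3o=self.satisfies_n3o(),
            paired_hierarchy=self.is_paired_hierarchy(),
            two_inc=self.satisfies_two_inc(),
        )

    # -- pre-pyramidality -------------------------------------------------------
    def is_pre_pyramidal(self) -> bool:
        """All clusters are intervals of some total order on X.

        Under (L) this is equivalent to (N3O); without (L) we fall back to an
        exhaustive backtracking search for a compatible order, permitted only
        for |X| <= 10.
        """
        if self.satisfies_L():
            return self.satisfies_n3o()
        if len(self.X) > 10:
            raise GroundSetTooLargeWithoutL(
                "pre-pyramidality without (L) is decided by exhaustive "
                f"order search; |X| = {len(self.X)} > 10"
            )
        elements = sorted(self.X)
        proper = [c for c in self.clusters if 1 < len(c) < len(self.X)]

        def consistent(prefix: List[str]) -> bool:
            for c in proper:
                pos = [i for i, x in enumerate(prefix) if x in c]
                if not pos:
                    continue
                lo, hi = pos[0], pos[-1]
                if hi - lo + 1 > len(pos):  # a gap inside the placed part of c
                    return False
                # a non-member was placed after c started while members of c
                # are still unplaced: c can never become an interval
                if hi < len(prefix) - 1 and len(pos) < len(c):
                    return False
            return True

        def extend(prefix: List[str], remaining: Set[str]) -> bool:
            if not remaining:
                return True
            for x in sorted(remaining):
                prefix.append(x)
                if consistent(prefix) and extend(prefix, remaining - {x}):
                    return True
                prefix.pop()
            return False

        return extend([], set(elements))


@dataclass(frozen=True)
class CsFlags:
    hierarchy: bool
    pre_binary: bool
    binary: bool
    weak_hierarchy: bool
    property_L: bool
    n3o: bool
    paired_hierarchy: bool
    two_inc: bool


class ClusterMultiset:
    """M_N: one cluster count per vertex of the originating network."""

    def __init__(self, counts: Dict[Cluster, int]):
        self.counts: Dict[Cluster, int] = {
            frozenset(c): int(m) for c, m in counts.items()
        }
        if any(m <= 0 for m in self.counts.values()):
            raise InvalidClusteringSystem("multiplicities must be positive")

    def __getitem__(self, c: Iterable[str]) -> int:
        return self.counts.get(frozenset(c), 0)

    def __eq__(self, other) -> bool:
        return isinstance(other, ClusterMultiset) and self.counts == other.counts

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __len__(self) -> int:
        return sum(self.counts.values())

    def support(self) -> FrozenSet[Cluster]:
        return frozenset(self.counts)

    def max_multiplicity(self) -> int:
        return max(self.counts.values())

    def canonical(self) -> Tuple[Tuple[Tuple[str, ...], int], ...]:
        return tuple(sorted((_key(c), m) for c, m in self.counts.items()))

    def __repr__(self) -> str:
        inner = ", ".join(
            "{" + ",".join(k) + "}:" + str(m) for k, m in self.canonical()
        )
        return f"ClusterMultiset({inner})"


# --- network-facing operations ------------------------------------------------
def cluster_of(n: Network, v: VertexId) -> Cluster:
    return n.cluster(v)


def clustering_system(n: Network) -> ClusteringSystem:
    """C_N as a set; always a valid clustering system."""
    return ClusteringSystem(n.labels, {n.cluster(v) for v in n.vertices})


def cluster_multiset(n: Network) -> ClusterMultiset:
    counts = Counter(n.cluster(v) for v in n.vertices)
    return ClusterMultiset(dict(counts))


def closure_of(cs: ClusteringSystem, a: Iterable[str]) -> Cluster:
    return cs.closure_of(a)


def is_closed(cs: ClusteringSystem) -> bool:
    return cs.is_closed()


def intersection_closure(cs: ClusteringSystem) -> ClusteringSystem:
    return cs.intersection_closure()


def cs_flags(cs: ClusteringSystem) -> CsFlags:
    return cs.flags()


def is_pre_pyramidal(cs: ClusteringSystem) -> bool:
    return cs.is_pre_pyramidal()
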